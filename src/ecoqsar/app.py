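"""End-to-end pipeline: score -> align -> fields -> fit -> predict -> design
-> screen -> coupling, with YAML configuration and per-stage CSV outputs.

The pipeline is a thin orchestration of the library modules.  Each stage
writes its table under the output directory; a stage failure aborts the run
with the stage named, keeping the outputs written so far.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .chem_core import MinimizationSettings, Molecule3D, prepare
from .comsia import (
    GridSettings,
    PLSModel,
    align_to_template,
    choose_n_components,
    compute_fields,
    contour_map,
    core_mapping,
    descriptor_matrix,
    model_stats,
    pls_fit,
    write_opendx,
    write_point_csv,
)
from .comsia.align import _kabsch
from .coupling import coupling_table, group_summaries, pearson_r
from .design import ScreenRules, SubstitutionPlan, enumerate_derivatives, evaluate_derivatives, screen
from .fixtures import group_fragments, group_volumes, load_fixture, load_sites
from .flammability import PHTHALATE_SMARTS
from .ideal_point import IdealPointConfig, score_table

__all__ = ["EndpointSpec", "EndpointModel", "PipelineConfig", "PipelineError",
           "fit_endpoint", "run_pipeline", "validate_config"]

log = logging.getLogger("ecoqsar")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class EndpointSpec:
    """One QSAR endpoint: which response to model and which template to align on."""

    name: str
    response_column: str
    template_id: str
    transform: str = "none"  # none | log10

    def response(self, table: pd.DataFrame) -> pd.Series:
        y = table[self.response_column].astype(float)
        if self.transform == "log10":
            y = np.log10(y)
        elif self.transform != "none":
            raise ValueError(f"unknown transform {self.transform!r}")
        return y


@dataclass
class EndpointModel:
    """A fitted endpoint: PLS model plus the lattice and aligned template."""

    name: str
    model: PLSModel
    grid: object  # FieldGrid of the training set
    template: Molecule3D
    core_smarts: str
    seed: int
    stats: object | None = None
    align_rmsd: dict[str, float] = dc_field(default_factory=dict)

    def predict_molecule(self, mol: Molecule3D) -> float:
        """Embed/parameterize if needed, align onto the template core, predict."""
        if mol.coords is None or mol.partial_charges is None:
            from rdkit import Chem

            smiles = Chem.MolToSmiles(mol.rdkit_mol)
            mol = prepare(smiles, mol.id, MinimizationSettings(random_seed=self.seed))
        from rdkit import Chem

        patt = Chem.MolFromSmarts(self.core_smarts)
        match = mol.rdkit_mol.GetSubstructMatch(patt)
        t_match = self.template.rdkit_mol.GetSubstructMatch(patt)
        if not match or not t_match:
            raise ValueError(f"{mol.id}: molecule or template lacks the alignment core")
        R, t = _kabsch(mol.coords[list(match)], self.template.coords[list(t_match)])
        aligned = mol.copy()
        aligned.coords = mol.coords @ R.T + t
        grid = compute_fields([aligned], grid=self.grid)
        x, _ = descriptor_matrix(grid, [aligned.id])
        return float(self.model.predict(x)[0])


def fit_endpoint(
    table: pd.DataFrame,
    spec: EndpointSpec,
    grid_settings: GridSettings | None = None,
    seed: int = 42,
    core_smarts: str = PHTHALATE_SMARTS,
    max_components: int | None = None,
) -> EndpointModel:
    """Build one endpoint model from a table with id/smiles/split columns."""
    ids = list(table["id"])
    y = spec.response(table).to_numpy()
    settings = MinimizationSettings(random_seed=seed)
    mols = [prepare(smi, mid, settings) for mid, smi in zip(ids, table["smiles"])]
    aln_spec = core_mapping(mols, spec.template_id, core_smarts)
    aln = align_to_template(mols, aln_spec)
    grid = compute_fields(aln.molecules, grid_settings or GridSettings())
    X, labels = descriptor_matrix(grid, ids)

    split = table["split"] if "split" in table.columns else pd.Series("train", index=table.index)
    train = (split == "train").to_numpy()
    test = ~train
    n, q2 = choose_n_components(X[train], y[train], max_components)
    model = pls_fit(X[train], y[train], n, field_labels=labels)
    stats = model_stats(model, X[train], y[train],
                        X[test] if test.any() else None,
                        y[test] if test.any() else None, q2=q2)
    template = next(m for m in aln.molecules if m.id == spec.template_id)
    return EndpointModel(name=spec.name, model=model, grid=grid, template=template,
                         core_smarts=core_smarts, seed=seed, stats=stats,
                         align_rmsd=aln.rmsd)


@dataclass
class PipelineConfig:
    """Pipeline inputs and stage switches; see validate_config for the checks."""

    out_dir: str = "ecoqsar_out"
    property_table: str | None = None  # CSV path; packaged 17-PAE table if None
    ideal_config: IdealPointConfig = dc_field(default_factory=IdealPointConfig)
    endpoints: list[EndpointSpec] = dc_field(default_factory=list)
    grid_settings: GridSettings = dc_field(default_factory=GridSettings)
    seed: int = 42
    design_parents: list[str] = dc_field(default_factory=list)
    design_groups: list[str] | None = None  # None -> all packaged groups
    design_mode: str = "single"
    screen_rules: ScreenRules = dc_field(default_factory=ScreenRules)
    run_screen_on_reference: bool = True
    run_coupling: bool = True
    map_fields: list[str] = dc_field(default_factory=list)

    def config_hash(self) -> str:
        blob = repr(self).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def validate_config(config: "PipelineConfig | dict") -> list[str]:
    """Return a list of problems; empty iff the config is runnable.

    Accepts either a constructed :class:`PipelineConfig` or the raw mapping
    parsed from a YAML file, so that invalid values (e.g. weights that do not
    sum to 1) are reported as problems instead of raising.
    """
    if isinstance(config, dict):
        problems = []
        raw = dict(config)
        for section, ctor in (("ideal_config", IdealPointConfig),
                              ("grid_settings", GridSettings),
                              ("screen_rules", ScreenRules)):
            if section in raw:
                params = dict(raw.pop(section))
                for key, val in params.items():
                    if isinstance(val, list):
                        params[key] = tuple(val)
                try:
                    ctor(**params)
                except (TypeError, ValueError) as exc:
                    problems.append(f"{section}: {exc}")
        specs = raw.pop("endpoints", [])
        try:
            endpoints = [EndpointSpec(**e) for e in specs]
        except TypeError as exc:
            problems.append(f"endpoints: {exc}")
            endpoints = []
        try:
            base = PipelineConfig(endpoints=endpoints, **raw)
        except TypeError as exc:
            problems.append(f"config: {exc}")
            return problems
        return problems + validate_config(base)

    problems: list[str] = []
    try:
        IdealPointConfig(**vars(config.ideal_config))
    except (TypeError, ValueError) as exc:
        problems.append(f"ideal_config: {exc}")
    if config.property_table is not None and not Path(config.property_table).exists():
        problems.append(f"property_table: file not found: {config.property_table}")
    names = [e.name for e in config.endpoints]
    if len(set(names)) != len(names):
        problems.append(f"endpoints: duplicate names in {names}")
    for e in config.endpoints:
        if e.transform not in ("none", "log10"):
            problems.append(f"endpoint {e.name}: unknown transform {e.transform!r}")
    known_parents = set(load_sites())
    for p in config.design_parents:
        if p not in known_parents:
            problems.append(f"design parent {p!r} has no site definition "
                            f"(known: {sorted(known_parents)})")
    if config.design_mode not in ("single", "double", "both"):
        problems.append(f"design_mode must be single/double/both, got {config.design_mode!r}")
    try:
        ScreenRules(**vars(config.screen_rules))
    except (TypeError, ValueError) as exc:
        problems.append(f"screen_rules: {exc}")
    return problems


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages; returns a summary dict (also written as JSON)."""
    problems = validate_config(config)
    if problems:
        raise PipelineError("validate", ValueError("; ".join(problems)))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"config_hash": config.config_hash(), "seed": config.seed,
                     "stages": []}

    def stage(name):
        summary["stages"].append(name)
        log.info("stage %s", name)

    # --- score ---------------------------------------------------------
    try:
        stage("score")
        if config.property_table is None:
            table = load_fixture("table1")
        else:
            table = pd.read_csv(config.property_table)
        result = score_table(table.set_index("id"), config.ideal_config)
        scored = table.set_index("id").copy()
        scored["Z_computed"] = result.Z
        scored.to_csv(out / "scores.csv")
        summary["n_scored"] = int(len(scored))
    except Exception as exc:
        raise PipelineError("score", exc) from exc

    # --- QSAR endpoints ------------------------------------------------
    models: dict[str, EndpointModel] = {}
    if config.endpoints:
        for espec in config.endpoints:
            try:
                stage(f"fit:{espec.name}")
                if espec.response_column == "Z_computed":
                    fit_table = scored.reset_index()
                else:
                    fit_table = table
                em = fit_endpoint(fit_table, espec, config.grid_settings,
                                  seed=config.seed)
                models[espec.name] = em
                em.model.to_json(out / f"model_{espec.name}.json")
                st = em.stats
                pd.DataFrame([{
                    "endpoint": espec.name, "n_components": em.model.n_components,
                    "q2": st.q2, "r2": st.r2, "SEE": st.SEE, "F": st.F,
                    "r2_pred": st.r2_pred, "SEP": st.SEP,
                    **{f"frac_{k}": v for k, v in (st.field_contributions or {}).items()},
                }]).to_csv(out / f"stats_{espec.name}.csv", index=False)
                for fname in config.map_fields:
                    cmap = contour_map(em.model, em.grid, fname)
                    write_opendx(cmap, out / f"map_{espec.name}_{fname}.dx")
                    write_point_csv(cmap, out / f"map_{espec.name}_{fname}.csv")
            except Exception as exc:
                raise PipelineError(f"fit:{espec.name}", exc) from exc

    # --- design + prediction ------------------------------------------
    if config.design_parents and models:
        try:
            stage("design")
            sites = load_sites()
            fragments = group_fragments()
            if config.design_groups is not None:
                fragments = {g: fragments[g] for g in config.design_groups}
            frames = []
            for parent in config.design_parents:
                plan = SubstitutionPlan(
                    parent_id=parent,
                    parent_smiles=sites[parent]["smiles"],
                    sites=sites[parent]["sites"],
                    groups=fragments,
                    mode=config.design_mode,
                )
                derivs = enumerate_derivatives(plan)
                parent_values = {
                    name: em.predict_molecule(prepare(
                        sites[parent]["smiles"], parent,
                        MinimizationSettings(random_seed=config.seed)))
                    for name, em in models.items()
                }
                predictors = {name: em.predict_molecule for name, em in models.items()}
                frames.append(evaluate_derivatives(derivs, predictors, parent_values))
            designed = pd.concat(frames, ignore_index=True)
            designed.to_csv(out / "derivatives.csv", index=False)
            summary["n_derivatives"] = int(len(designed))
        except Exception as exc:
            raise PipelineError("design", exc) from exc

    # --- screen --------------------------------------------------------
    if config.run_screen_on_reference:
        try:
            stage("screen")
            t7 = load_fixture("table7")
            records = t7[t7["parent"].notna() & (t7["parent"] != "")]
            screened = screen(records, config.screen_rules)
            screened.to_csv(out / "screened.csv", index=False)
            summary["n_screen_input"] = int(len(records))
            summary["n_screen_pass"] = int(screened["passes"].sum())
        except Exception as exc:
            raise PipelineError("screen", exc) from exc

    # --- coupling ------------------------------------------------------
    if config.run_coupling:
        try:
            stage("coupling")
            t9 = load_fixture("table9")
            cdf = coupling_table(t9, group_volumes())
            cdf.to_csv(out / "coupling.csv", index=False)
            t7 = load_fixture("table7")
            summaries = group_summaries(cdf, t7[t7["parent"].notna()])
            summaries.to_csv(out / "group_summaries.csv", index=False)
            r1 = pearson_r(summaries["group_properties_pct"],
                           summaries["comprehensive_effect_pct"])
            r2 = pearson_r(summaries["comprehensive_effect_pct"],
                           summaries["weighted_comprehensive_effect_pct"])
            summary["R_coupling_vs_effect"] = r1["R"]
            summary["R_effect_vs_weighted"] = r2["R"]
        except Exception as exc:
            raise PipelineError("coupling", exc) from exc

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=str)
    _write_report(out, summary)
    return summary


def _write_report(out: Path, summary: dict) -> None:
    lines = ["# ecoqsar pipeline report", "",
             f"config hash: {summary['config_hash']}  seed: {summary['seed']}", "",
             f"stages run: {', '.join(summary['stages'])}", ""]
    if "n_scored" in summary:
        lines.append(f"- molecules scored: {summary['n_scored']}")
    if "n_derivatives" in summary:
        lines.append(f"- derivatives designed: {summary['n_derivatives']}")
    if "n_screen_pass" in summary:
        lines.append(f"- screening funnel: {summary['n_screen_input']} -> "
                     f"{summary['n_screen_pass']}")
    if "R_coupling_vs_effect" in summary:
        lines.append(f"- R(coupling, comprehensive effect) = "
                     f"{summary['R_coupling_vs_effect']:.4f}")
        lines.append(f"- R(comprehensive, weighted single effects) = "
                     f"{summary['R_effect_vs_weighted']:.4f}")
    (out / "report.md").write_text("\n".join(lines) + "\n")


def load_config(path) -> PipelineConfig:
    """Read a pipeline config from YAML (flat keys mirroring PipelineConfig)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs = {}
    if "ideal_config" in raw:
        ic = raw.pop("ideal_config")
        for key in ("indices", "directions", "weights"):
            if key in ic:
                ic[key] = tuple(ic[key])
        kwargs["ideal_config"] = IdealPointConfig(**ic)
    if "grid_settings" in raw:
        kwargs["grid_settings"] = GridSettings(**raw.pop("grid_settings"))
    if "screen_rules" in raw:
        sr = raw.pop("screen_rules")
        if "koa_band" in sr:
            sr["koa_band"] = tuple(sr["koa_band"])
        kwargs["screen_rules"] = ScreenRules(**sr)
    if "endpoints" in raw:
        kwargs["endpoints"] = [EndpointSpec(**e) for e in raw.pop("endpoints")]
    kwargs.update(raw)
    return PipelineConfig(**kwargs)
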
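# Methods

This note records the models implemented in `ecoqsar`, the defaults and why
they were chosen, the numerical conventions, and the known limits of what
the tests demonstrate.

## Empirical flammability (module `flammability`)

For halogen-free organics the limited oxygen index correlates with the char
residue left at 850 °C:

    LOI [%] = 17.5 + 0.4 · CR,      CR = 1200 · Σ(CFT)ᵢ / M

`(CFT)ᵢ` is a per-functional-group char-forming contribution and `M` the
molecular weight in g/mol.  The benzene-1,2-diester (phthalate) moiety is
matched once per molecule by SMARTS and contributes CFT = 2; all other
halogen-free groups contribute 0.  This single assignment reproduces the
packaged LOI reference for all 17 PAEs to ±0.005, which is the strongest
available evidence for the convention (matched once, not per ester).  LOI
is therefore affine in 1/M across the family and strictly decreasing in M —
both are asserted as properties.  Molar masses use RDKit's standard atomic
weights with implicit hydrogens counted.

Derivative molecules are *not* pushed through this formula by default:
substituents introduced during design would each need their own CFT value,
which is not available; derivative LOI comes from the QSAR model instead.
`CFTTable` accepts user-supplied SMARTS→CFT entries (YAML) for other
chemistries.

## Ideal-point scoring (module `ideal_point`)

Raw indices are min–max normalized over the molecule set; inverse indices
(smaller is better, e.g. log *BCF*) are flipped so that 1 is always the
preferred end.  The comprehensive value is the weighted distance from the
all-ones ideal point:

    euclidean (default):  Z = sqrt( Σⱼ λⱼ (Cⱼ − 1)² )
    manhattan (option) :  Z = Σⱼ λⱼ |Cⱼ − 1|

Default weights λ = (0.4, 0.3, 0.3) over (flammability, biotoxicity,
enrichment); biotoxicity is normalized on the **raw** LC₅₀ in mg/L, not its
logarithm — this is forced by reproducing the packaged reference scores.
The euclidean form is the default because only it reproduces those scores
(the metric is also conventionally described as a euclidean distance); the
manhattan form is retained behind `metric="manhattan"` for completeness.
Degenerate (constant) columns raise an error naming the column rather than
silently mapping to 0 or 1.  Ties in the ranking break lexicographically by
molecule id.

## 3D structure preparation (module `chem_core`)

SMILES/MOL input is parsed by RDKit with a deterministic atom order.  One
conformer is generated per molecule by ETKDG distance geometry from a fixed
seed and relaxed with MMFF94 (UFF fallback), with an energy tolerance of
0.005 kcal/mol and at most 10 000 iterations — the conventional
convergence settings for this kind of force-field minimization.  A single
seeded conformer (not an ensemble) is used throughout; identical seed gives
bitwise-identical coordinates.

Per-atom field parameters: Gasteiger iterative electronegativity-
equalization charges (the Hückel π-correction of some commercial packages
is proprietary; plain Gasteiger conserves total charge to 1e-3 and respects
molecular symmetry, which is what downstream code relies on); steric
volumes as r³ of the van der Waals radius; hydrophobicity as Crippen atomic
logP contributions; donor/acceptor flags from O–H/N–H/S–H and lone-pair
SMARTS rules.

## Similarity-index fields and PLS (module `comsia`)

Molecules are rigidly superposed on a template over mapped core atoms
(Kabsch least-squares; the phthalate skeleton mapping can be derived
automatically by substructure match).  Fields are evaluated on one shared
axis-aligned lattice enclosing every aligned molecule:

    A_F(q) = − Σ_atoms w_probe,F · w_atom,F · exp(−α · r²)

with α = 0.3 and a unit probe (charge +1 e, radius 1 Å, hydrophobicity +1,
donor/acceptor +1) — the conventional similarity-index settings.  Grid
defaults: 2.0 Å spacing, 4.0 Å margin.  The fields are linear in the atomic
parameters and equivariant under rigid motions of molecules + lattice; both
are asserted in tests.

PLS1 is implemented as NIPALS with X- and y-centering (no scaling); the
regression vector is `W(PᵀW)⁻¹q`.  An independent reference implementation
agrees to 1e-8 and is used only as a test oracle.  Near-constant lattice
columns are dropped before fitting; the range threshold is expressed as a
configurable fraction of a 125.4 energy-style cutoff, defaulting to
exact-degeneracy only, and is documented rather than load-bearing (removing
sub-threshold columns changes fitted r² by far less than 0.05 on the
fixtures).

Statistics: LOO q² = 1 − PRESS/SS by honest refitting with each sample
excluded (equal to a brute-force loop to 1e-10); r² = 1 − RSS/SS;
SEE = √(RSS/(m−n−1)); F = (r²/n)/((1−r²)/(m−n−1)); external validation
uses r²_pred = 1 − PRESS_test/SD_test with SD_test about the *training*
mean, and SEP = √(PRESS_test/m_test).  The m−n−1 denominator convention is
stated here because several are in circulation.  Adequacy flags: q² > 0.5,
r² > 0.9, r²_pred > 0.6.  Model selection maximizes LOO q² subject to
n ≤ m−2; larger n (e.g. 10 components from 13 samples) is possible only by
explicit override, since it exceeds conventional limits.

Field contributions are Σ|coef·stdev| per field block, normalized to 100 %,
reported in S, E, H, D, A order.  Contour maps are per-point StDev*Coeff
values; favored points are above the 80th percentile of positive values,
disfavored below the 20th percentile of negative values; export as OpenDX
grid plus point-list CSV.

Field blocks are **not** variance-scaled against each other, so on real
molecules the steric block (r³ values of tens of Å⁻³-scale units) dominates
the contribution split.  This is a known limitation of the unscaled
convention, kept because it preserves the linearity properties the tests
rely on; the fractions on real data should be read qualitatively.

## Synthetic validation sets (module `synthetic`)

Toy rigid molecules share a four-atom scaffold with fixed parameters; each
adds 3 substituent atoms near random scaffold corners with randomized
parameters.  The response is a planted linear functional of the stacked
descriptors — a Gaussian-localized steric-rewarding region plus a
hydrophobicity-penalizing region (length scale 2 Å), mimicking a receptor
pocket — normalized to unit signal stdev, plus Gaussian noise given either
as an absolute σ or a signal-to-noise stdev ratio.  Defaults: 20 molecules,
2 Å lattice with 3 Å margin (≈1260 descriptors).  Everything is a pure
function of the seed.

At zero noise the full-rank fit is exact and LOO q² is near 1; at
signal:noise 3 the engine recovers q² > 0.5 in at least 90 of 100 seeds and
the fitted functional correlates > 0.9 with the planted one.  Because the
planted coefficient vector has large components outside the 20-sample row
space, coefficient-vector correlation is not a meaningful recovery metric;
the functional-value correlation is used instead.  What passing these tests
shows: the field/PLS/LOO machinery is correct and sensitive at realistic
noise.  What it does not show: that any particular real-world field
parameterization or alignment reproduces a specific published model — with
only 17 heterogeneous molecules, absolute q² on real data depends strongly
on proprietary field and alignment details, which is why the real-data
model statistics are validated structurally, not numerically.

## Design and screening (module `design`)

Modification sites are the terminal side-chain carbons of each parent
(the ester methyls of DMP, the terminal vinyl carbons of DAP), shipped as an
editable `sites.yaml` keyed by heavy-atom index.  Attachment replaces one
hydrogen at the site with a fragment carrying a single `[*]` attachment
point; valence failures are recorded per product without aborting the
enumeration.  Names are canonical `parent-site-group`.

Percent changes follow the improvement sign conventions of the reference
tables: a "decrease" column is positive when the value fell (Z, log *BCF*),
an "increase" column positive when it rose (LOI, log *LC₅₀*).  Screening
rules: all four effects improved strictly, LOI gain above 5 %,
log *BCF* < 3.30 (non-bioaccumulative), log *K*OA within [6.5, 10]
(semi-volatile), Freq > 0 (vibrationally stable).  Freq and energy-gap are
input columns only — quantum chemistry is out of scope — so the stability
rule is skipped with a warning when the column is absent.  Screening is
monotone in its thresholds.  The exact enumeration that produced the
reference 38-derivative set is not recoverable, so the reference derivative
names ship as fixtures while the enumerator stays generic.

## Group coupling (module `coupling`)

Coupling = 0.229·ΔVol% + 0.449·ΔlogP%, the steric and hydrophobic field
fractions of the multi-effect model used as decimals *without*
renormalizing by their sum — forced by cell-level reproduction of the
reference coupling table.  Volumes come from a shipped lookup (H = 1.0,
CH₃ = 15.0, …, CH₂C₆H₅ = 91.1) because the original volume method is not
stated; logP baselines are the parent molecules, also for double
substitutions.  Group summaries average over all derivatives carrying the
group **that appear in the effect table** (one reference derivative has
coupling inputs but no effect row; including it would break the reproduced
means), and groups left without members are omitted with a warning.
The weighted comprehensive effect combines flammability/biotoxicity/
enrichment means at 0.4/0.3/0.3.  Pearson correlations are flagged against
two-sided t-based critical values (n = 8: 0.7067 at P = 0.05, 0.8343 at
P = 0.01).

## Pipeline, problem sizes, and determinism

The `app` module chains score → fit → design → screen → coupling behind a
YAML config with one seed feeding every stochastic stage (embedding,
synthetic generation); reruns are byte-identical.  A stage failure aborts
with the stage named and keeps partial outputs.  Tests run the full
17-molecule fit on a 3 Å lattice and the synthetic engine at its default
20-molecule/1260-descriptor size, which keeps the whole suite under a
minute while exercising every code path at full fidelity; the packaged
defaults (2 Å lattice) are what `examples/03` uses.

## Known limitations

- Single-conformer treatment; no conformational ensembles or tautomers.
- Gasteiger charges are a fast approximation; quantum-chemical charges are
  out of scope.
- Unscaled field blocks make the steric channel dominate contribution
  fractions on real molecules (see above).
- The 125.4-cutoff column filter is a documented analog of an ambiguous
  legacy setting, not a reconstruction of it.
- Ecotoxicity inputs (LC₅₀, BCF, HL, KOA) and Freq/energy-gap values are
  consumed as data; the package never predicts them from first principles.
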
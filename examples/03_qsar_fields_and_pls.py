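"""A 3D-QSAR model of the comprehensive score on the 17 plasticizers.

Each molecule is embedded in 3D, parameterized (Gasteiger charges, steric
volumes, atomic logP, donor/acceptor flags), aligned on the shared phthalate
skeleton, and described by similarity-index fields on a common lattice.  A
NIPALS PLS model then regresses the comprehensive score Z on the fields,
with the number of latent components chosen by leave-one-out q2.  The field
contribution fractions say which interaction type drives the model.
"""

from ecoqsar.app import EndpointSpec, fit_endpoint
from ecoqsar.comsia import GridSettings, contour_map
import ecoqsar as eq

table1 = eq.load_fixture("table1")
endpoint = fit_endpoint(
    table1,
    EndpointSpec(name="multi_effect", response_column="Z", template_id="DMEP"),
    GridSettings(spacing=2.0, margin=4.0),
    seed=7,
)

st = endpoint.stats
print(f"components n = {endpoint.model.n_components}")
print(f"LOO q2   = {st.q2:.3f}   (predictive above 0.5)")
print(f"r2       = {st.r2:.3f}   SEE = {st.SEE:.3f}   F = {st.F:.1f}")
if st.r2_pred is not None:
    print(f"r2_pred  = {st.r2_pred:.3f}   SEP = {st.SEP:.3f}  (external test set)")
print("field contributions (%):",
      {k: round(v, 1) for k, v in st.field_contributions.items()})

cmap = contour_map(endpoint.model, endpoint.grid, "S")
print(f"steric StDev*Coeff map: {cmap.favored_mask.sum()} favored / "
      f"{cmap.disfavored_mask.sum()} disfavored lattice points")
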
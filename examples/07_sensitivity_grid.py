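"""N-rate x residue sensitivity on cluster-representative fields.

Clusters a dry landscape, picks each cluster's medoid field, and runs
the emission model over N multipliers (1.0-2.0 of the 125 kg/ha
schedule) crossed with residue-retention fractions (0-100 %).
"""

from paddyghg import (
    ScenarioGrid,
    descriptor_table,
    find_medoid,
    generate_landscape,
    kmeans_fit,
    run_grid,
    standardize,
)
from paddyghg.synthetic import SurrogateParams

land = generate_landscape("dry", 160, seed=1)
Z, scaling = standardize(descriptor_table(land.series))
model = kmeans_fit(Z, 5, scaling=scaling, seed=0)
medoids = {
    int(c): find_medoid(model.assignments.index[model.assignments == c], Z,
                        model.centroids.loc[c])
    for c in model.centroids.index
}
print("medoid field per cluster:", medoids)

noise_free = SurrogateParams(ch4_noise_sd_log=0.0, n2o_noise_sd_log=0.0)
df = run_grid(medoids, {s.field_id: s for s in land.series},
              {r["field_id"]: r for r in land.soils.to_dict("records")},
              land.management, ScenarioGrid(), noise_free)

full_residue = df[(df.n_multiplier == 1.0) & (df.residue_fraction == 1.0)]
print("\nCH4 gain from full residue retention (kg/ha, vs none):")
print(full_residue.set_index("cluster")["delta_ch4_kg_ha"].round(1).to_string())
double_n = df[(df.n_multiplier == 2.0) & (df.residue_fraction == 0.0)]
print("\nN2O gain from doubling the N rate (g/ha, vs baseline):")
print(double_n.set_index("cluster")["delta_n2o_g_ha"].round(1).to_string())
print("\nResidue carbon matters only where fields stay flooded (wet")
print("clusters); extra fertilizer N raises N2O everywhere.")
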
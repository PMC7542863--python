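"""Generate the study-scale synthetic district fixture.

Builds the 20x32 lattice (n = 640, the administrative scale of the real
system), draws covariates matching the published district-level marginals,
and simulates a cervical-screening outcome under the spatial error process
at lambda = 0.69 with the calibrated innovation SD.  Writes GeoJSON + CSV +
a JSON sidecar of the true parameters under results/fixture/.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

import spatscreen as ss

OUT = Path(__file__).resolve().parents[1] / "results" / "fixture"
SEED = 11


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    spec = ss.LatticeSpec()
    ids, geoms = ss.make_lattice(spec)
    w = ss.build_queen_weights(geoms, ids).row_standardized()
    tab = ss.simulate_covariates(ss.default_variable_specs(), spec.n, seed=7)
    x, beta, names = ss.study_design(tab)
    y, truth = ss.simulate_outcome(
        w, x, ss.DgpConfig("sem", tuple(beta), ss.DEFAULT_LAMBDA, seed=SEED)
    )
    tab.insert(0, "unit_id", ids)
    tab["cervical_screening"] = y
    area = ss.AreaTable(ids=ids, geometries=geoms, attributes=tab.set_index("unit_id"))
    ss.write_geojson(area, OUT / "lattice.geojson")
    tab.to_csv(OUT / "attributes.csv", index=False, float_format="%.12g")
    (OUT / "truth.json").write_text(json.dumps(truth, indent=1, sort_keys=True) + "\n")
    summary = ss.summarize_variables(tab.set_index("unit_id"))
    summary.to_csv(OUT / "summary_statistics.csv", float_format="%.4f")
    print(f"n={spec.n} districts; outcome generated under {truth['process']} "
          f"with spatial parameter {truth['spatial_param']}")
    print(f"fixture written to {OUT}")


if __name__ == "__main__":
    main()
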
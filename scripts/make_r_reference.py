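"""Regenerate tests/data/moran_reference.json.

Writes the deterministic cross-check cases (value vector + dense weight
matrix) to scratch/r_reference/, runs ape::Moran.I over them via
scripts/make_r_reference.R, and freezes the reference statistics as JSON.
Rerunning is only needed if the fixture definitions below change.
"""

from __future__ import annotations

import json
import subprocess
import sys
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

import spatscreen as ss  # noqa: E402

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "r_reference"
OUT = ROOT / "tests" / "data" / "moran_reference.json"


def fixture_cases() -> dict[str, tuple[np.ndarray, ss.SpatialWeights]]:
    """Deterministic (x, W) cases shared with tests/test_cross_checks.py."""
    cases: dict[str, tuple[np.ndarray, ss.SpatialWeights]] = {}

    # 4-node path graph, hand-buildable
    neighbors = [np.array(v) for v in ([1], [0, 2], [1, 3], [2])]
    w_path = ss.SpatialWeights(
        ids=[str(i) for i in range(4)],
        neighbors=neighbors,
        weights=[np.ones(len(v)) for v in neighbors],
        style="binary",
    )
    x_path = np.array([1.0, 2.0, 3.0, 4.0])
    # ape::Moran.I row-standardizes the supplied matrix internally, so only
    # row-standardized cases are meaningful references; binary-style checks
    # use the brute-force oracle in the tests instead.
    cases["path4_row"] = (x_path, w_path.row_standardized())

    # 5x5 queen lattice with a simulated covariate
    ids, geoms = ss.make_lattice(ss.LatticeSpec(rows=5, cols=5))
    w5 = ss.build_queen_weights(geoms, ids)
    x5 = ss.simulate_covariates(ss.default_variable_specs(), 25, seed=42)[
        "cervical_screening"
    ].to_numpy()
    cases["lattice5_row"] = (x5, w5.row_standardized())

    # study-scale 20x32 lattice with an SEM outcome
    spec = ss.LatticeSpec()
    ids, geoms = ss.make_lattice(spec)
    wrow = ss.build_queen_weights(geoms, ids).row_standardized()
    tab = ss.simulate_covariates(ss.default_variable_specs(), spec.n, seed=7)
    xmat, beta_true, _ = ss.study_design(tab)
    y, _ = ss.simulate_outcome(
        wrow, xmat, ss.DgpConfig(process="sem", beta=tuple(beta_true), seed=11)
    )
    cases["lattice640_sem_row"] = (y, wrow)
    return cases


def main() -> None:
    SCRATCH.mkdir(parents=True, exist_ok=True)
    for name, (x, w) in fixture_cases().items():
        np.savetxt(SCRATCH / f"{name}_x.csv", x, delimiter=",")
        np.savetxt(SCRATCH / f"{name}_w.csv", w.dense(), delimiter=",")
    res = subprocess.run(
        ["Rscript", str(ROOT / "scripts" / "make_r_reference.R"), str(SCRATCH)],
        capture_output=True,
        text=True,
        check=True,
    )
    ref = json.loads(res.stdout)
    OUT.parent.mkdir(parents=True, exist_ok=True)
    OUT.write_text(json.dumps(ref, indent=1, sort_keys=True) + "\n")
    print(f"wrote {OUT}: {ref}")


if __name__ == "__main__":
    main()
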
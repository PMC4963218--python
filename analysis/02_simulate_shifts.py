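#!/usr/bin/env python
"""Simulate surrogate ¹³C shift records for the ensembles built by
01_build_ensembles.py.

Each conformation gets a shift made of a base value, a smooth torsion
response shared by paired twins, a zero-sum rotamer offset, the calibrated
modification effect, and Gaussian observation noise (0.5 ppm).  Writes one
CSV per state and side under results/shifts/.
"""

from pathlib import Path

from ptmdelta.serialization import read_manifest
from ptmdelta.surrogate import SurrogateParams, load_calibration, simulate_shift_records

SEED = 42
OUT = Path(__file__).resolve().parents[1] / "results"


def main():
    (OUT / "shifts").mkdir(parents=True, exist_ok=True)
    calibration = load_calibration()
    manifests = sorted((OUT / "ensembles").glob("*.json"))
    if not manifests:
        raise SystemExit("run analysis/01_build_ensembles.py first")
    for k, path in enumerate(manifests):
        d = read_manifest(path)
        params = SurrogateParams(seed=SEED + 10 * k + 1)
        mod, unmod = simulate_shift_records(d, calibration, params)
        tag = path.stem
        mod.to_csv(OUT / "shifts" / f"{tag}_mod.csv", index=False)
        unmod.to_csv(OUT / "shifts" / f"{tag}_unmod.csv", index=False)
        entry = calibration[(d["residue"], d["state"])]
        print(f"{tag:<28} {len(mod):>5} modified records  "
              f"effect {entry.effect:+.1f} ppm ({entry.anchor})")
    print(f"\nwrote shift tables to {OUT / 'shifts'}")


if __name__ == "__main__":
    main()
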
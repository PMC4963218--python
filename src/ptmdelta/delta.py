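"""Δ distributions: rotamer averaging, mean-centering on the unmodified
ensemble, and kernel-density summaries.

The Δ value of a conformation is its ¹³C shift minus the mean shift of the
matched *non-modified* ensemble.  Unmodified Δ samples are therefore centered
on 0 ppm by construction, and any constant reference offset cancels.
Rotamer averaging happens in shift space, before Δ and before any density
estimate: for states whose modification introduces an internal rotation the
per-backbone value is the arithmetic mean over the enumerated rotamers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .topology import RotamerScheme

__all__ = [
    "DeltaDistribution",
    "average_over_rotamers",
    "compute_delta",
    "kde_density",
    "pool_states",
]


def average_over_rotamers(records: pd.DataFrame,
                          scheme: RotamerScheme | None = None) -> pd.DataFrame:
    """Average shift records over rotamers, one record per backbone index.

    If a ``scheme`` with enumerated rotamers is given, every backbone index
    must carry a record for each rotamer of the scheme (missing rotamers are
    reported).  Single-rotamer and sampled (glycan) schemes pass through with
    one record per backbone unchanged.
    """
    if scheme is not None and scheme.enumerated and len(scheme.labels) > 1:
        expected = set(scheme.labels)
        for bb, grp in records.groupby("backbone_index"):
            missing = expected - set(grp["rotamer"])
            if missing:
                raise ValueError(
                    f"backbone index {bb} is missing rotamers {sorted(missing)}"
                )
    if records["backbone_index"].value_counts().max() == 1:
        return records.copy()
    first = records.groupby("backbone_index", as_index=False).first()
    means = records.groupby("backbone_index", as_index=False)["value"].mean()
    out = first.drop(columns=["value"]).merge(means, on="backbone_index")
    out["rotamer"] = "averaged"
    return out[records.columns]


def compute_delta(modified: pd.DataFrame, unmodified: pd.DataFrame,
                  ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Δ samples for both ensembles: value − mean(unmodified values).

    Both inputs must be shift-kind records of the same nucleus (convert
    shieldings first).  The unmodified side's Δ mean is exactly zero.
    """
    for side, df in (("modified", modified), ("unmodified", unmodified)):
        if df.empty:
            raise ValueError(f"{side} records are empty")
        if not (df["kind"] == "shift").all():
            raise ValueError(f"{side} records must be shifts; convert "
                             "shieldings with to_shift() first")
    nuclei = set(modified["nucleus"]) | set(unmodified["nucleus"])
    if len(nuclei) != 1:
        raise ValueError(f"nucleus mismatch across sides: {sorted(nuclei)}")
    center = unmodified["value"].mean()

    def deltas(df: pd.DataFrame) -> pd.DataFrame:
        out = df[["backbone_index", "residue", "state", "nucleus"]].copy()
        out["delta"] = df["value"] - center
        return out

    return deltas(modified), deltas(unmodified)


@dataclass
class DeltaDistribution:
    """Δ samples for one (residue, state, nucleus) plus a Gaussian-kernel KDE."""

    residue: str
    state: str
    nucleus: str
    samples: np.ndarray
    grid: np.ndarray
    density: np.ndarray
    bandwidth: float
    mean: float
    sd: float
    mode: float

    @property
    def n(self) -> int:
        return self.samples.size

    def summary(self) -> dict:
        return {"residue": self.residue, "state": self.state,
                "nucleus": self.nucleus, "n": self.n, "mean": self.mean,
                "sd": self.sd, "mode": self.mode, "bandwidth": self.bandwidth}


def kde_density(samples, residue: str = "", state: str = "", nucleus: str = "",
                bandwidth: float | str = "silverman",
                grid_points: int = 512) -> DeltaDistribution:
    """Gaussian-kernel KDE of Δ samples on a uniform grid.

    Bandwidth follows Silverman's rule unless an explicit value (ppm) is
    given; the grid spans the samples ± 4 bandwidths.  The reported mode is
    the density argmax over the grid, ties broken toward smaller Δ.
    """
    samples = np.asarray(samples, dtype=float).ravel()
    if samples.size < 2:
        raise ValueError("KDE requires at least 2 samples")
    if isinstance(bandwidth, str):
        kde = gaussian_kde(samples, bw_method=bandwidth)
    else:
        kde = gaussian_kde(samples, bw_method=bandwidth / samples.std(ddof=1))
    bw = float(kde.factor * samples.std(ddof=1))
    lo, hi = samples.min() - 4 * bw, samples.max() + 4 * bw
    grid = np.linspace(lo, hi, grid_points)
    density = kde(grid)
    mode = float(grid[int(np.argmax(density))])  # argmax returns first (smaller Δ) tie
    return DeltaDistribution(
        residue=residue, state=state, nucleus=nucleus, samples=samples,
        grid=grid, density=density, bandwidth=bw,
        mean=float(samples.mean()), sd=float(samples.std(ddof=1)), mode=mode,
    )


def pool_states(distributions: list[DeltaDistribution], label: str,
                bandwidth: float | str = "silverman") -> DeltaDistribution:
    """Concatenate Δ samples of several states and re-estimate the density
    (e.g. condensing mono-Nε and mono-Nη methylation into "mono-methylated")."""
    if not distributions:
        raise ValueError("nothing to pool")
    nuclei = {d.nucleus for d in distributions}
    if len(nuclei) != 1:
        raise ValueError(f"cannot pool across nuclei: {sorted(nuclei)}")
    residues = {d.residue for d in distributions}
    samples = np.concatenate([d.samples for d in distributions])
    return kde_density(samples, residue="/".join(sorted(residues)), state=label,
                       nucleus=nuclei.pop(), bandwidth=bandwidth)
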
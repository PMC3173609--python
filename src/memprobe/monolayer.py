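"""Critical surface pressure from Langmuir monolayer penetration series.

Protein injected under a lipid monolayer at initial surface pressure π₀
raises the pressure by Δπ; Δπ falls roughly linearly with π₀, and the
x-intercept of the least-squares line Δπ = a + b·π₀ is the critical
pressure π_c — the monolayer pressure beyond which the protein can no
longer penetrate.  Wild-type GRP1-PH reaches π_c ≈ 28 mN/m at pH 7.4;
loop mutants that penetrate less give lower π_c.  All pressures in mN/m.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PenetrationSeries",
    "CriticalPressure",
    "fit_critical_pressure",
    "compare_constructs",
]


@dataclass
class PenetrationSeries:
    """(π₀, Δπ) measurements for one construct on one lipid composition."""

    pi0: np.ndarray  # mN/m
    dpi: np.ndarray  # mN/m
    construct: str = "WT"
    composition: str = ""

    def __post_init__(self) -> None:
        self.pi0 = np.asarray(self.pi0, dtype=float)
        self.dpi = np.asarray(self.dpi, dtype=float)
        if self.pi0.shape != self.dpi.shape or self.pi0.size < 2:
            raise ValueError("need >= 2 matched (pi0, dpi) points")

    @classmethod
    def read(cls, path, construct: str | None = None) -> list["PenetrationSeries"]:
        """Read a TSV/CSV with columns pi0, dpi[, construct]; one series per construct."""
        df = pd.read_csv(path, sep=None, engine="python")
        if "construct" not in df.columns:
            df["construct"] = construct or "WT"
        out = []
        for name, grp in df.groupby("construct", sort=False):
            out.append(cls(grp["pi0"].to_numpy(), grp["dpi"].to_numpy(),
                           construct=str(name)))
        return out


@dataclass
class CriticalPressure:
    pi_c: float  # mN/m, x-intercept
    slope: float  # dimensionless (mN/m per mN/m)
    intercept: float  # mN/m at pi0 = 0
    r_squared: float
    n_points: int
    construct: str = "WT"
    method: str = "OLS x-intercept extrapolation of dpi vs pi0"


def fit_critical_pressure(series: PenetrationSeries) -> CriticalPressure:
    """Least-squares line Δπ = a + b·π₀; π_c = −a/b.

    Replicate π₀ values are averaged before fitting (unweighted).  A
    non-negative slope means Δπ does not decay with π₀ and no penetration
    limit can be extrapolated → error.
    """
    df = pd.DataFrame({"pi0": series.pi0, "dpi": series.dpi})
    df = df.groupby("pi0", as_index=False).mean()
    if len(df) < 2 or np.ptp(df["pi0"].to_numpy()) < 1e-12:
        raise ValueError("pi0 values must not be constant")
    fit = stats.linregress(df["pi0"], df["dpi"])
    if fit.slope >= 0:
        raise ValueError("no extrapolable penetration limit: slope >= 0")
    return CriticalPressure(
        pi_c=float(-fit.intercept / fit.slope),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue ** 2),
        n_points=int(len(df)),
        construct=series.construct)


def compare_constructs(series_set: list[PenetrationSeries]) -> pd.DataFrame:
    """Rank constructs by fitted π_c and report differences vs the wild type.

    The reference is the construct named "WT" when present, otherwise the
    highest-π_c construct.  Output sorted by π_c descending.
    """
    if len(series_set) < 2:
        raise ValueError("need at least two constructs to compare")
    fits = [fit_critical_pressure(s) for s in series_set]
    ref = next((f for f in fits if f.construct == "WT"),
               max(fits, key=lambda f: f.pi_c))
    rows = [dict(construct=f.construct, pi_c=f.pi_c, slope=f.slope,
                 r_squared=f.r_squared, n_points=f.n_points,
                 delta_vs_ref=f.pi_c - ref.pi_c) for f in fits]
    out = pd.DataFrame(rows).sort_values("pi_c", ascending=False,
                                         ignore_index=True)
    out.attrs["reference"] = ref.construct
    return out
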
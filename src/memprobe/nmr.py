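"""HSQC chemical-shift-perturbation (CSP) analysis.

Amide resonances are compared between a reference ("free") and a perturbed
("bound", e.g. micelle-associated) condition.  Per residue the ¹H and ¹⁵N
shift changes are combined as

    Δδ = sqrt(Δδ_H² + (α·Δδ_N)²),   α = 0.2 by default,

the usual amide normalisation that weights nitrogen by its relative shift
dispersion.  A residue is significant when its Δδ strictly exceeds the
dataset mean plus one standard deviation; the large/medium split at
mean + 2·SD mirrors two-tier structure colouring.  The threshold is
recomputed for every dataset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PeakList",
    "CSPTable",
    "SignificanceRule",
    "combined_csp",
    "csp_table",
    "classify_significant",
    "compare_ph_series",
    "micellar_concentration",
]


@dataclass
class PeakList:
    """Per-residue amide peak positions under one condition."""

    table: pd.DataFrame  # residue_id, residue_name, h_ppm, n_ppm
    condition: str = ""

    def __post_init__(self) -> None:
        required = {"residue_id", "residue_name", "h_ppm", "n_ppm"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"peak list missing columns {sorted(missing)}")
        if self.table["residue_id"].duplicated().any():
            raise ValueError("one peak per residue per condition")
        if not np.isfinite(self.table[["h_ppm", "n_ppm"]].to_numpy()).all():
            raise ValueError("shifts must be finite")

    @classmethod
    def read(cls, path, condition: str = "") -> "PeakList":
        df = pd.read_csv(path, sep=None, engine="python")
        return cls(df, condition=condition)

    def write(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


@dataclass
class CSPTable:
    """Per-residue shift changes, combined perturbation and significance class."""

    table: pd.DataFrame  # residue_id, residue_name, d_h, d_n, d_combined[, csp_class]
    missing: pd.DataFrame | None = None  # residues present in only one condition
    alpha: float = 0.2
    threshold: float | None = None  # mean + n_sd*SD once classified

    def significant(self) -> pd.DataFrame:
        if "csp_class" not in self.table.columns:
            raise ValueError("run classify_significant first")
        return self.table[self.table["csp_class"] != "none"]


@dataclass
class SignificanceRule:
    """Threshold = mean + n_sd·SD of the combined CSPs; strict >."""

    n_sd: float = 1.0
    large_n_sd: float = 2.0

    def __post_init__(self) -> None:
        if self.large_n_sd < self.n_sd:
            raise ValueError("large_n_sd must be >= n_sd")


def combined_csp(d_h, d_n, alpha: float = 0.2):
    """Combined amide shift change sqrt(dH² + (α·dN)²) in ppm (broadcasts)."""
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    return np.sqrt(np.square(d_h) + np.square(alpha * np.asarray(d_n, dtype=float)))


def csp_table(free: PeakList, bound: PeakList, alpha: float = 0.2) -> CSPTable:
    """Residue-matched shift differences (bound − free) and combined CSPs.

    Residues present in only one list are reported under ``missing`` and
    excluded from any downstream statistics — never silently dropped.
    """
    f = free.table.set_index("residue_id")
    b = bound.table.set_index("residue_id")
    shared = f.index.intersection(b.index)
    if len(shared) == 0:
        raise ValueError("peak lists share no residues")
    if len(shared) < 3:
        raise ValueError("need at least 3 shared residues")
    d_h = (b.loc[shared, "h_ppm"] - f.loc[shared, "h_ppm"]).to_numpy()
    d_n = (b.loc[shared, "n_ppm"] - f.loc[shared, "n_ppm"]).to_numpy()
    out = pd.DataFrame(dict(
        residue_id=shared.to_numpy(),
        residue_name=f.loc[shared, "residue_name"].to_numpy(),
        d_h=d_h, d_n=d_n,
        d_combined=combined_csp(d_h, d_n, alpha)))
    only = f.index.symmetric_difference(b.index)
    missing = None
    if len(only):
        src = pd.concat([f.loc[f.index.intersection(only)],
                         b.loc[b.index.intersection(only)]])
        missing = src.reset_index()[["residue_id", "residue_name"]]
    return CSPTable(out.reset_index(drop=True), missing=missing, alpha=alpha)


def classify_significant(table: CSPTable,
                         rule: SignificanceRule | None = None) -> CSPTable:
    """Attach significance classes using the mean + n·SD rule.

    Classes: large (> mean + large_n_sd·SD), medium (> mean + n_sd·SD), else
    none.  Degenerate all-equal input (SD = 0) yields no significant
    residues because the comparison is strict.
    """
    rule = rule or SignificanceRule()
    values = table.table["d_combined"].to_numpy(dtype=float)
    if len(values) < 3:
        raise ValueError("need at least 3 combined CSP values")
    mean = float(np.mean(values))
    sd = float(np.std(values))  # population SD; recomputed per dataset
    threshold = mean + rule.n_sd * sd
    large_threshold = mean + rule.large_n_sd * sd
    cls = np.full(len(values), "none", dtype=object)
    cls[values > threshold] = "medium"
    if sd > 0:
        cls[values > large_threshold] = "large"
    out = table.table.copy()
    out["csp_class"] = cls
    return CSPTable(out, missing=table.missing, alpha=table.alpha,
                    threshold=threshold)


def compare_ph_series(tables: dict[float, CSPTable]) -> pd.DataFrame:
    """Per-residue monotonicity of the combined CSP as pH decreases.

    ``tables`` maps pH → CSPTable.  Each shared residue is flagged
    ``increasing`` when Δδ grows strictly at every step down in pH,
    ``flat`` when constant, otherwise ``non-monotone``.  A ``fraction
    increasing`` summary row accompanies the table via the attrs dict.
    """
    if len(tables) < 2:
        raise ValueError("need at least two pH conditions")
    phs = sorted(tables, reverse=True)  # decreasing pH order
    frames = {ph: tables[ph].table.set_index("residue_id")["d_combined"]
              for ph in phs}
    shared = frames[phs[0]].index
    for ph in phs[1:]:
        shared = shared.intersection(frames[ph].index)
    if len(shared) == 0:
        raise ValueError("no residues shared across pH conditions")
    rows = []
    for res in shared:
        series = np.array([frames[ph].loc[res] for ph in phs])
        steps = np.diff(series)
        if np.all(steps > 1e-12):
            flag = "increasing"
        elif np.all(np.abs(steps) <= 1e-12):
            flag = "flat"
        else:
            flag = "non-monotone"
        rows.append(dict(residue_id=res, trend=flag,
                         **{f"d_combined_pH{ph:g}": v for ph, v in zip(phs, series)}))
    out = pd.DataFrame(rows)
    out.attrs["fraction_increasing"] = float((out["trend"] == "increasing").mean())
    out.attrs["ph_order"] = phs
    return out


def micellar_concentration(c_detergent_mM: float,
                           aggregation_number: float = 56.0) -> float:
    """Solution concentration of intact micelles (mM).

    Detergent monomer concentration divided by the mean aggregation number
    (56 for DPC): 286 mM detergent → 5.1 mM micellar.
    """
    if c_detergent_mM <= 0 or aggregation_number <= 0:
        raise ValueError("concentration and aggregation number must be positive")
    return c_detergent_mM / aggregation_number


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures (reporting helper)."""
    if x == 0:
        return 0.0
    from math import floor, log10

    return round(x, -int(floor(log10(abs(x)))) + (sig - 1))
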
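"""Spearman correlation / partial-correlation screen.

For every strongly positively correlated lncRNA (X) and mRNA (Y) pair, each
miRNA (Z) is scored by the sensitivity S_Z: the drop of the X-Y Spearman
correlation when Z is partialled out.  Large positive S_Z implicates Z in
the X-Y association.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_SENSITIVITY_THRESHOLD = 0.2
DEFAULT_RHO_MIN = 0.5
DEFAULT_P_MAX = 0.05


class DegenerateConditioningError(ValueError):
    """Conditioning variable perfectly correlated with X or Y."""


@dataclass
class CorrelationRecord:
    """One (lncRNA, miRNA, mRNA) triplet with its screen statistics."""

    lncrna: str
    mirna: str
    mrna: str
    rho_xy: float
    rho_xy_p: float
    rho_xz: float
    rho_yz: float
    rho_xy_given_z: float
    s_z: float
    passes_threshold: bool

    def to_dict(self) -> dict:
        return asdict(self)


def spearman(x, y) -> tuple[float, float]:
    """Spearman rho and its two-sided p-value (t-approximation).

    rho is the Pearson correlation of average ranks (ties get the mean
    rank); p comes from the large-sample test of rho = 0 with n - 2
    degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    rho = float(np.corrcoef(stats.rankdata(x), stats.rankdata(y))[0, 1])
    p = _spearman_p(rho, x.size)
    return rho, p


def _spearman_p(rho: float, n: int) -> float:
    if abs(rho) >= 1.0:
        return 0.0
    t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def partial_spearman(rho_xy: float, rho_xz: float, rho_yz: float) -> float:
    """First-order partial correlation of X and Y given Z."""
    if abs(rho_xz) >= 1.0 or abs(rho_yz) >= 1.0:
        raise DegenerateConditioningError(
            "|rho_xz| or |rho_yz| is 1; partial correlation undefined"
        )
    denom = np.sqrt(1.0 - rho_xz**2) * np.sqrt(1.0 - rho_yz**2)
    return float((rho_xy - rho_xz * rho_yz) / denom)


def sensitivity(rho_xy: float, rho_xy_given_z: float) -> float:
    """S_Z = rho_XY - rho_XY|Z."""
    return float(rho_xy - rho_xy_given_z)


def _rank_rows(df: pd.DataFrame) -> np.ndarray:
    return np.apply_along_axis(stats.rankdata, 1, df.to_numpy(dtype=float))


def _cross_corr(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise Pearson correlation between all rows of a and b."""
    az = (a - a.mean(axis=1, keepdims=True))
    bz = (b - b.mean(axis=1, keepdims=True))
    az /= np.linalg.norm(az, axis=1, keepdims=True)
    bz /= np.linalg.norm(bz, axis=1, keepdims=True)
    return np.clip(az @ bz.T, -1.0, 1.0)


def screen_candidates(
    m,
    t: float = DEFAULT_SENSITIVITY_THRESHOLD,
    rho_min: float = DEFAULT_RHO_MIN,
    p_max: float = DEFAULT_P_MAX,
) -> list[CorrelationRecord]:
    """Exhaustive triplet screen over a preprocessed matrix.

    Keeps lncRNA:mRNA pairs with rho_XY > ``rho_min`` and p < ``p_max``;
    for each kept pair emits one record per miRNA with
    ``passes_threshold = (S_Z >= t)``.
    """
    lnc = m.of_class("lncRNA")
    mrna = m.of_class("mRNA")
    mir = m.of_class("miRNA")
    for name, df in (("lncRNA", lnc), ("mRNA", mrna), ("miRNA", mir)):
        if df.empty:
            raise ValueError(f"matrix has no rows of class {name}")

    n = m.n_samples
    rl, rg, rm = _rank_rows(lnc), _rank_rows(mrna), _rank_rows(mir)
    rho_lg = _cross_corr(rl, rg)           # lnc x mrna
    rho_lm = _cross_corr(rl, rm)           # lnc x mirna
    rho_gm = _cross_corr(rg, rm)           # mrna x mirna

    records: list[CorrelationRecord] = []
    lnc_ids, mrna_ids, mir_ids = lnc.index, mrna.index, mir.index
    for i, j in zip(*np.where(rho_lg > rho_min)):
        rho_xy = float(rho_lg[i, j])
        p_xy = _spearman_p(rho_xy, n)
        if p_xy >= p_max:
            continue
        rho_xz = rho_lm[i]
        rho_yz = rho_gm[j]
        denom = np.sqrt((1.0 - rho_xz**2) * (1.0 - rho_yz**2))
        with np.errstate(divide="ignore", invalid="ignore"):
            rho_cond = (rho_xy - rho_xz * rho_yz) / denom
        s = rho_xy - rho_cond
        for k, mir_id in enumerate(mir_ids):
            records.append(
                CorrelationRecord(
                    lncrna=str(lnc_ids[i]),
                    mirna=str(mir_id),
                    mrna=str(mrna_ids[j]),
                    rho_xy=rho_xy,
                    rho_xy_p=p_xy,
                    rho_xz=float(rho_xz[k]),
                    rho_yz=float(rho_yz[k]),
                    rho_xy_given_z=float(rho_cond[k]),
                    s_z=float(s[k]),
                    passes_threshold=bool(np.isfinite(s[k]) and s[k] >= t),
                )
            )
    return records


def records_to_frame(records: list[CorrelationRecord]) -> pd.DataFrame:
    cols = list(CorrelationRecord.__dataclass_fields__)
    if not records:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame([r.to_dict() for r in records], columns=cols)
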
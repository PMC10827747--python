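"""qPCR concordance: ΔΔCt subspecies shares and regression agreement
with computational estimates.

qPCR with subspecies-specific primer pairs yields one Ct per target per
sample.  Assuming ~100% primer efficiency, a Ct difference of ΔCt
cycles between the two targets corresponds to a 2^−ΔCt abundance fold;
converted to shares of the two subspecies summing to 1.  ``agreement``
regresses qPCR shares on the computational shares (ordinary least
squares) — the standard wet-lab validation of a marker-based
quantifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .core import SubmarkerError

__all__ = ["CtTable", "AgreementResult", "ddct_ratio", "agreement"]


@dataclass
class CtTable:
    """qPCR measurements: rows of (sample_id, target, ct, replicate)."""

    rows: list[tuple[str, str, float, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for s, t, ct, rep in self.rows:
            if not ct > 0:
                raise ValueError(f"sample {s}, target {t}: Ct must be > 0, got {ct}")

    @property
    def samples(self) -> list[str]:
        out: list[str] = []
        for s, *_ in self.rows:
            if s not in out:
                out.append(s)
        return out

    @property
    def targets(self) -> list[str]:
        out: list[str] = []
        for _, t, *_ in self.rows:
            if t not in out:
                out.append(t)
        return out

    def mean_ct(self, sample_id: str, target: str) -> float:
        cts = [ct for s, t, ct, _ in self.rows if s == sample_id and t == target]
        if not cts:
            raise SubmarkerError(f"sample {sample_id!r}: no Ct for target {target!r}")
        return float(np.mean(cts))


@dataclass(frozen=True)
class AgreementResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


def ddct_ratio(
    table: CtTable,
    sample_id: str,
    target_a: str,
    target_b: str,
    efficiency: Optional[float] = None,
) -> tuple[float, float]:
    """Within-sample two-target ΔCt ratio as subspecies shares.

    Replicate Cts are averaged per target; fold = E^−(Ct_A − Ct_B) with
    amplification base E = 2 (perfect doubling) unless an efficiency is
    given (E = 1 + efficiency).  Returns (share_A, share_B) summing
    to 1: equal Cts give (0.5, 0.5); Ct_A one cycle lower gives
    (2/3, 1/3).
    """
    ct_a = table.mean_ct(sample_id, target_a)
    ct_b = table.mean_ct(sample_id, target_b)
    base = 2.0 if efficiency is None else 1.0 + efficiency
    fold = base ** (-(ct_a - ct_b))
    return fold / (1.0 + fold), 1.0 / (1.0 + fold)


def agreement(
    computational: Sequence[tuple[str, float]] | Mapping[str, float],
    qpcr: Sequence[tuple[str, float]] | Mapping[str, float],
    min_n: int = 3,
) -> AgreementResult:
    """OLS of qPCR shares on computational shares over shared samples.

    Returns slope, intercept, R² and the two-sided t-test p-value on
    the slope.  Requires >= ``min_n`` shared samples and non-constant
    computational values.
    """
    comp = dict(computational)
    q = dict(qpcr)
    shared = sorted(set(comp) & set(q))
    if len(shared) < min_n:
        raise ValueError(f"need >= {min_n} shared samples, got {len(shared)}")
    x = np.array([comp[s] for s in shared], dtype=float)
    y = np.array([q[s] for s in shared], dtype=float)
    if np.allclose(x, x[0]):
        raise SubmarkerError("degenerate regression: computational shares constant")
    fit = stats.linregress(x, y)
    return AgreementResult(slope=float(fit.slope), intercept=float(fit.intercept),
                           r_squared=float(fit.rvalue) ** 2,
                           p_value=float(fit.pvalue), n=len(shared))
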
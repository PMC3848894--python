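"""CoMi activity scoring: miRNA-GOBP pair enumeration, the hypergeometric
overlap filter, per-sample Welch-t activity scores, and profile assembly.

A CoMi (context-specific miRNA activity) score contrasts, within one GO
biological-process term and one sample, the expression of a miRNA's target
genes against the term's non-target genes with a two-sample t statistic.
Pairs whose target/term intersection is too small (< 10 genes by default) or
not significant under the hypergeometric test (p > 0.05) are discarded before
any scoring.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from math import comb, floor, sqrt

import numpy as np
import pandas as pd

from .data_io import GeneSetCollection
from .errors import DataError

logger = logging.getLogger(__name__)


def hypergeom_tail(x: int, M: int, K: int, N: int) -> float:
    """Upper-tail hypergeometric probability P(X >= x).

    X counts successes when drawing N items without replacement from a
    universe of M items of which K are marked: here, how many of a GO term's
    N genes are among a miRNA's K targets in a universe of M genes.

    Computed with exact integer arithmetic (the final division is a single
    correctly rounded float), so the result is exact to double precision for
    any M up to at least 1e5.
    """
    for name, val in (("x", x), ("M", M), ("K", K), ("N", N)):
        if int(val) != val or val < 0:
            raise ValueError(f"{name} must be a nonnegative integer, got {val!r}")
    x, M, K, N = int(x), int(M), int(K), int(N)
    if K > M or N > M:
        raise ValueError(f"K={K} and N={N} must not exceed M={M}")
    if x > min(K, N):
        raise ValueError(f"x={x} exceeds min(K, N)={min(K, N)}")
    lo = max(0, K + N - M)  # smallest achievable overlap
    if x <= lo:
        return 1.0
    hi = min(K, N)
    # integer recurrence over the unnormalized pmf; one division at the end
    term = comb(K, x) * comb(M - K, N - x)
    total = term
    for i in range(x, hi):
        term = term * (K - i) * (N - i) // ((i + 1) * (M - K - N + i + 1))
        total += term
    return total / comb(M, N)


@dataclass(frozen=True)
class MiRnaGobpPair:
    """One miRNA paired with one GO-BP term it significantly intersects."""

    mirna_id: str
    gobp_id: str
    in_term_targets: frozenset[str]
    in_term_nontargets: frozenset[str]
    K: int  # all targets of the miRNA in the universe
    N: int  # term size in the universe
    M: int  # universe size
    p_overlap: float

    @property
    def x(self) -> int:
        return len(self.in_term_targets)

    @property
    def key(self) -> tuple[str, str]:
        return (self.mirna_id, self.gobp_id)


def enumerate_pairs(
    targets: GeneSetCollection,
    gobp: GeneSetCollection,
    expr: pd.DataFrame,
    min_intersection: int = 10,
    alpha: float = 0.05,
    min_nontargets: int = 3,
) -> list[MiRnaGobpPair]:
    """Enumerate and filter miRNA-GOBP pairs.

    The gene universe is the intersection of the measured genes with the
    union of all GO-term members; every set is restricted to that universe
    before counting.  A pair survives when its intersection has at least
    *min_intersection* genes, the hypergeometric tail probability is at most
    *alpha*, and at least *min_nontargets* term genes are not targets (the t
    statistic needs a variance from each group).

    Order is deterministic: miRNAs in target-GMT load order (outer), terms in
    GO-GMT load order (inner).
    """
    if len(targets) == 0 or len(gobp) == 0:
        raise DataError("empty gene-set collection")
    universe = frozenset(expr.index) & gobp.union()
    M = len(universe)
    if M == 0:
        raise DataError("empty universe: no measured gene is GO-annotated")
    term_sets = {g: gobp.as_set(g) & universe for g in gobp}
    pairs: list[MiRnaGobpPair] = []
    for mirna in targets:
        tset = targets.as_set(mirna) & universe
        K = len(tset)
        if K == 0:
            continue
        for term in gobp:
            gset = term_sets[term]
            N = len(gset)
            inter = tset & gset
            x = len(inter)
            if x < min_intersection:
                continue
            nontargets = gset - tset
            if len(nontargets) < min_nontargets:
                continue
            p = hypergeom_tail(x, M, K, N)
            if p <= alpha:
                pairs.append(
                    MiRnaGobpPair(
                        mirna_id=mirna,
                        gobp_id=term,
                        in_term_targets=frozenset(inter),
                        in_term_nontargets=frozenset(nontargets),
                        K=K,
                        N=N,
                        M=M,
                        p_overlap=p,
                    )
                )
    return pairs


def _welch_t_rows(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Columnwise Welch t between target rows X (n x S) and non-target rows Y (m x S).

    Sign convention: positive when targets exceed non-targets.  Columns where
    either group has < 2 finite values, or where the pooled standard error is
    zero with unequal means, come back NaN; zero standard error with equal
    means gives 0.
    """
    with np.errstate(invalid="ignore", divide="ignore"):
        nx = np.sum(np.isfinite(X), axis=0).astype(float)
        ny = np.sum(np.isfinite(Y), axis=0).astype(float)
        sx = np.nansum(X, axis=0)
        sy = np.nansum(Y, axis=0)
        mx = np.where(nx > 0, sx / np.maximum(nx, 1), np.nan)
        my = np.where(ny > 0, sy / np.maximum(ny, 1), np.nan)
        ssx = np.nansum((X - mx) ** 2, axis=0)
        ssy = np.nansum((Y - my) ** 2, axis=0)
        vx = np.where(nx >= 2, ssx / np.maximum(nx - 1, 1), np.nan)
        vy = np.where(ny >= 2, ssy / np.maximum(ny - 1, 1), np.nan)
        diff = mx - my
        se2 = vx / nx + vy / ny
        t = diff / np.sqrt(se2)
        t = np.where(se2 == 0, np.where(diff == 0, 0.0, np.nan), t)
        t = np.where((nx < 2) | (ny < 2), np.nan, t)
    return t


def comi_score(expr: pd.DataFrame, pair: MiRnaGobpPair, sample: str) -> float:
    """CoMi activity of one pair in one sample (scalar convenience form)."""
    col = expr[sample]
    x = col.loc[sorted(pair.in_term_targets)].to_numpy(float)[:, None]
    y = col.loc[sorted(pair.in_term_nontargets)].to_numpy(float)[:, None]
    return float(_welch_t_rows(x, y)[0])


def build_profile(expr: pd.DataFrame, pairs: list[MiRnaGobpPair]) -> pd.DataFrame:
    """Score every pair in every sample; features x samples matrix.

    Features degenerate in any sample (fewer than two usable values in either
    group, or an infinite-t situation) are dropped with a logged count.
    """
    if not pairs:
        raise DataError("no pairs to score")
    values = expr.to_numpy(float)
    row_of = {g: i for i, g in enumerate(expr.index)}
    rows = []
    keys = []
    for pair in pairs:
        t_idx = [row_of[g] for g in sorted(pair.in_term_targets) if g in row_of]
        n_idx = [row_of[g] for g in sorted(pair.in_term_nontargets) if g in row_of]
        rows.append(_welch_t_rows(values[t_idx], values[n_idx]))
        keys.append(pair.key)
    mat = np.vstack(rows)
    ok = np.isfinite(mat).all(axis=1)
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.warning("build_profile: dropped %d feature(s) degenerate in >= 1 sample", n_dropped)
    if not ok.any():
        raise DataError("all CoMi features degenerate")
    index = pd.MultiIndex.from_tuples(
        [k for k, keep in zip(keys, ok) if keep], names=["mirna_id", "gobp_id"]
    )
    return pd.DataFrame(mat[ok], index=index, columns=expr.columns)


def filter_profile(profile: pd.DataFrame, drop_fraction: float = 0.10) -> pd.DataFrame:
    """Noise-reduce a CoMi profile.

    First the ``floor(drop_fraction * n_rows)`` rows with the smallest
    variance across samples are discarded (variance ties keep the earlier
    row); then rows exactly equal to an earlier surviving row are removed,
    keeping the first occurrence.  Surviving row order is preserved.
    """
    if not 0 <= drop_fraction < 1:
        raise DataError(f"drop_fraction must be in [0, 1), got {drop_fraction}")
    if profile.shape[0] == 0:
        raise DataError("empty profile")
    n = profile.shape[0]
    n_drop = floor(drop_fraction * n)
    variances = profile.to_numpy().var(axis=1, ddof=1)
    # drop the n_drop smallest; among equal variances the later row goes first
    order = sorted(range(n), key=lambda i: (variances[i], -i))
    dropped = set(order[:n_drop])
    seen: set[bytes] = set()
    keep: list[int] = []
    for i in range(n):
        if i in dropped:
            continue
        sig = profile.iloc[i].to_numpy().tobytes()
        if sig in seen:
            continue
        seen.add(sig)
        keep.append(i)
    return profile.iloc[keep]
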
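"""Mean evolutionary divergence within and between groups.

Distances are uncorrected p-distances (base differences per compared site)
over aligned sequences.  Under pairwise deletion, any site where either
sequence of a pair carries a gap or 'N' is excluded from that pair's
numerator and denominator; under complete deletion, columns containing a
gap/'N' in *any* sequence are removed before all comparisons.  Group means
average over all unordered sequence pairs, each unique sequence counted
once regardless of read abundance.  Standard errors come from a
site-resampling bootstrap: alignment columns are resampled with
replacement, the means recomputed, and the SE taken as the standard
deviation over replicates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import AlignmentError, IgsflowError
from .seqio import SequenceRecord

_ACGT = np.frombuffer(b"ACGT", dtype=np.uint8)


def _to_matrix(seqs: Sequence[str]) -> np.ndarray:
    lengths = {len(s) for s in seqs}
    if len(lengths) > 1:
        raise AlignmentError(f"unequal sequence lengths {sorted(lengths)}")
    return np.vstack(
        [np.frombuffer(s.upper().encode(), dtype=np.uint8) for s in seqs]
    )


def _valid_mask(mat: np.ndarray) -> np.ndarray:
    return np.isin(mat, _ACGT)


def p_distance(a: str, b: str, deletion: str = "pairwise") -> float:
    """Proportion of differing bases over comparable sites of one pair.

    For a single pair, pairwise and complete deletion coincide.  Returns
    NaN (and raises nothing) when no site is comparable.
    """
    if deletion not in ("pairwise", "complete"):
        raise ValueError("deletion must be 'pairwise' or 'complete'")
    mat = _to_matrix([a, b])
    valid = _valid_mask(mat)
    both = valid[0] & valid[1]
    n = int(both.sum())
    if n == 0:
        return math.nan
    diffs = int(((mat[0] != mat[1]) & both).sum())
    return diffs / n


@dataclass
class DistanceSummary:
    """Within/between-group mean divergence with bootstrap standard errors.

    ``within[g]`` is NaN for groups of a single sequence.  ``between`` is a
    symmetric matrix over ``groups`` whose diagonal repeats ``within``.
    """

    groups: list[str]
    within: dict[str, float]
    between: np.ndarray
    se_within: dict[str, float]
    se_between: np.ndarray
    n_per_group: dict[str, int]

    def between_of(self, g: str, h: str) -> float:
        return float(self.between[self.groups.index(g), self.groups.index(h)])

    def to_frame(self):
        """Lower triangle = mean distances, upper triangle = SEs (table layout
        of the classic distance-summary presentation)."""
        import pandas as pd

        k = len(self.groups)
        out = np.full((k, k), np.nan)
        for i in range(k):
            out[i, i] = self.within.get(self.groups[i], np.nan)
            for j in range(k):
                if j < i:
                    out[i, j] = self.between[i, j]
                elif j > i:
                    out[i, j] = self.se_between[i, j]
        return pd.DataFrame(out, index=self.groups, columns=self.groups)


def _pair_indices(groups: Mapping[str, list[int]], g: str, h: str) -> list[tuple[int, int]]:
    if g == h:
        members = groups[g]
        return [(a, b) for ai, a in enumerate(members) for b in members[ai + 1 :]]
    return [(a, b) for a in groups[g] for b in groups[h]]


def _mean_over_pairs(
    diff: np.ndarray, both: np.ndarray, cols: np.ndarray | None
) -> float:
    """Mean p-distance over pairs, optionally on resampled columns.

    diff/both are per-pair per-column boolean matrices (pairs x sites).
    Pairs with zero comparable sites are skipped (reported upstream as NaN
    when all are).
    """
    if cols is not None:
        diff = diff[:, cols]
        both = both[:, cols]
    n = both.sum(axis=1)
    d = diff.sum(axis=1)
    ok = n > 0
    if not ok.any():
        return math.nan
    return float(np.mean(d[ok] / n[ok]))


def group_divergence(
    records: Sequence[SequenceRecord],
    group_of: Mapping[str, str],
    deletion: str = "pairwise",
    bootstrap_reps: int = 1000,
    seed: int | np.random.Generator | None = 0,
) -> DistanceSummary:
    """Within/between-group mean p-distance with site-bootstrap SEs.

    ``group_of`` maps record ids to group labels; every record needs a group.
    """
    if deletion not in ("pairwise", "complete"):
        raise ValueError("deletion must be 'pairwise' or 'complete'")
    if not records:
        raise IgsflowError("no sequences")
    for r in records:
        if r.id not in group_of:
            raise IgsflowError(f"record {r.id!r} has no group assignment")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    mat = _to_matrix([r.seq for r in records])
    valid = _valid_mask(mat)
    if deletion == "complete":
        keep = valid.all(axis=0)
        mat = mat[:, keep]
        valid = valid[:, keep]
    L = mat.shape[1]

    labels: list[str] = []
    members: dict[str, list[int]] = {}
    for i, r in enumerate(records):
        g = group_of[r.id]
        if g not in members:
            members[g] = []
            labels.append(g)
        members[g].append(i)

    k = len(labels)
    within: dict[str, float] = {}
    se_within: dict[str, float] = {}
    between = np.full((k, k), np.nan)
    se_between = np.full((k, k), np.nan)

    # precompute per-cell pair matrices lazily per group pair
    col_samples = (
        [rng.integers(0, L, size=L) for _ in range(bootstrap_reps)]
        if bootstrap_reps > 0 and L > 0
        else []
    )

    def summarise(pairs: Sequence[tuple[int, int]]) -> tuple[float, float]:
        if not pairs:
            return math.nan, math.nan
        ai = np.array([p[0] for p in pairs])
        bi = np.array([p[1] for p in pairs])
        both = valid[ai] & valid[bi]
        diff = (mat[ai] != mat[bi]) & both
        mean = _mean_over_pairs(diff, both, None)
        if not col_samples:
            return mean, math.nan
        reps = np.array([_mean_over_pairs(diff, both, cols) for cols in col_samples])
        reps = reps[~np.isnan(reps)]
        se = float(np.std(reps, ddof=1)) if len(reps) > 1 else math.nan
        return mean, se

    for i, g in enumerate(labels):
        if len(members[g]) >= 2:
            d, se = summarise(_pair_indices(members, g, g))
            within[g] = d
            se_within[g] = se
            between[i, i] = d
            se_between[i, i] = se
        else:
            within[g] = math.nan
            se_within[g] = math.nan
        for j in range(i + 1, k):
            h = labels[j]
            d, se = summarise(_pair_indices(members, g, h))
            between[i, j] = between[j, i] = d
            se_between[i, j] = se_between[j, i] = se

    return DistanceSummary(
        groups=labels,
        within=within,
        between=between,
        se_within=se_within,
        se_between=se_between,
        n_per_group={g: len(m) for g, m in members.items()},
    )


def intragenomic_divergence(
    aligned_variants: Sequence[SequenceRecord],
    bootstrap_reps: int = 1000,
    seed: int | np.random.Generator | None = 0,
    deletion: str = "pairwise",
) -> tuple[float, float]:
    """Mean pairwise p-distance among one sample's aligned unique variants.

    Unweighted over unique variants (read abundance plays no role).  Raises
    for fewer than two variants.
    """
    if len(aligned_variants) < 2:
        raise IgsflowError("intragenomic divergence needs >= 2 variants")
    group_of = {r.id: "sample" for r in aligned_variants}
    summary = group_divergence(
        aligned_variants,
        group_of,
        deletion=deletion,
        bootstrap_reps=bootstrap_reps,
        seed=seed,
    )
    return summary.within["sample"], summary.se_within["sample"]
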
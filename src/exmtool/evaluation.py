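"""Foreground-restricted Rand and information-theoretic segmentation scores.

Given a predicted segmentation ``X`` and ground truth ``Y`` on the same
grid, with ``n_ij`` the number of voxels jointly in predicted segment i
and true segment j:

* Rand split  = sum_ij n_ij^2 / sum_i (sum_j n_ij)^2
* Rand merge  = sum_ij n_ij^2 / sum_j (sum_i n_ij)^2
* VI split    = I(X, Y) / H(X)
* VI merge    = I(X, Y) / H(Y)

and each F-score is the harmonic mean of its split/merge pair.  All six
scores lie in [0, 1]; higher is better.  Foreground-restricted scoring
drops voxels that are boundary (membrane) in the ground truth, making the
scores insensitive to one-voxel border placement.

Note the printed conventions are kept literally: a strict over-segmentation
of the truth has perfect Rand *split* score and perfect VI *merge* score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse

from .volume import LabelVolume, extract_membrane

__all__ = ["ContingencyTable", "ScoreReport", "contingency", "rand_scores", "vi_scores", "score"]


@dataclass
class ContingencyTable:
    """Joint voxel counts between predicted and ground-truth segments."""

    counts: sparse.csr_matrix  # rows: predicted segments, cols: true segments
    restricted: bool

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class ScoreReport:
    rand_split: float
    rand_merge: float
    rand_f: float
    vi_split: float
    vi_merge: float
    vi_f: float

    def as_dict(self) -> dict[str, float]:
        return {
            "rand_split": self.rand_split,
            "rand_merge": self.rand_merge,
            "rand_f": self.rand_f,
            "vi_split": self.vi_split,
            "vi_merge": self.vi_merge,
            "vi_f": self.vi_f,
        }


def _harmonic(a: float, b: float) -> float:
    if a + b == 0:
        return 0.0
    return 2.0 * a * b / (a + b)


def contingency(
    pred: LabelVolume | np.ndarray,
    gt: LabelVolume | np.ndarray,
    foreground_restricted: bool = True,
) -> ContingencyTable:
    """Joint segment-overlap counts of a prediction against ground truth.

    When ``foreground_restricted`` is true, voxels on the ground-truth
    membrane (6-connectivity boundary of the ground-truth segments) are
    excluded from the counts.
    """
    p = pred.labels if isinstance(pred, LabelVolume) else np.asarray(pred)
    if isinstance(gt, LabelVolume):
        g_vol = gt
    else:
        g_vol = LabelVolume(np.ascontiguousarray(gt), voxel_size=1.0)
    g = g_vol.labels
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: pred {p.shape} vs gt {g.shape}")

    if foreground_restricted:
        keep = ~extract_membrane(g_vol).mask
    else:
        keep = np.ones(p.shape, dtype=bool)
    pv = p[keep].ravel()
    gv = g[keep].ravel()
    if pv.size == 0:
        raise ValueError("no voxels to evaluate after restriction")
    pi = np.unique(pv, return_inverse=True)[1]
    gi = np.unique(gv, return_inverse=True)[1]
    counts = sparse.coo_matrix(
        (np.ones(pv.size, dtype=np.int64), (pi, gi)),
        shape=(pi.max() + 1, gi.max() + 1),
    ).tocsr()
    return ContingencyTable(counts=counts, restricted=foreground_restricted)


def rand_scores(table: ContingencyTable) -> tuple[float, float, float]:
    """Rand split, merge and F-score from a contingency table."""
    c = table.counts
    if c.nnz == 0:
        raise ValueError("empty contingency table")
    ss = float((c.multiply(c)).sum())
    rows = np.asarray(c.sum(axis=1)).ravel().astype(float)
    cols = np.asarray(c.sum(axis=0)).ravel().astype(float)
    split = ss / float((rows**2).sum())
    merge = ss / float((cols**2).sum())
    return split, merge, _harmonic(split, merge)


def vi_scores(table: ContingencyTable) -> tuple[float, float, float]:
    """Information-theoretic split, merge and F-score.

    Entropies use natural logs (the ratios are base-invariant).  If one
    side is a single segment its entropy vanishes; the degenerate ratio is
    defined as 1 only when the segmentations are identical (then I = 0 =
    H), otherwise the table is genuinely uninformative and we raise.
    """
    c = table.counts.tocoo()
    if c.nnz == 0:
        raise ValueError("empty contingency table")
    n = float(c.sum())
    pij = c.data / n
    pi = np.asarray(table.counts.sum(axis=1)).ravel() / n
    pj = np.asarray(table.counts.sum(axis=0)).ravel() / n
    hx = float(-(pi[pi > 0] * np.log(pi[pi > 0])).sum())
    hy = float(-(pj[pj > 0] * np.log(pj[pj > 0])).sum())
    mi = float((pij * (np.log(pij) - np.log(pi[c.row]) - np.log(pj[c.col]))).sum())
    mi = max(mi, 0.0)

    if hx == 0.0 or hy == 0.0:
        if hx == hy == 0.0:
            return 1.0, 1.0, 1.0  # both single-segment and identical
        raise ValueError("single-segment segmentation: VI ratio undefined")
    split = mi / hx
    merge = mi / hy
    return split, merge, _harmonic(split, merge)


def score(
    pred: LabelVolume | np.ndarray,
    gt: LabelVolume | np.ndarray,
    foreground_restricted: bool = True,
    strict: bool = True,
) -> ScoreReport:
    """Convenience wrapper: full six-score report.

    With ``strict=False`` a degenerate single-segment prediction yields
    NaN VI scores instead of raising (useful when scanning hierarchy
    levels, where the coarsest level can be a single segment).
    """
    t = contingency(pred, gt, foreground_restricted)
    rs, rm, rf = rand_scores(t)
    try:
        vs, vm, vf = vi_scores(t)
    except ValueError:
        if strict:
            raise
        vs = vm = vf = float("nan")
    return ScoreReport(rs, rm, rf, vs, vm, vf)
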
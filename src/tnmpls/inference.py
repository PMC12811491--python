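"""Network-level interpretation of a component's connectivity weights.

A component's edge weights are embedded as a symmetric region-by-region
coefficient matrix; five edge blocks (within-SN, within-FPN, within-DMN,
SN–FPN, SN–DMN) are scored by their total absolute contribution and
tested against a permutation null that uniformly shuffles coefficients
over the allowed edge positions.  Per-region signed strengths (positive
and negative row sums) identify top contributing regions, and significant
blocks are summarized as a directed circuit in which between-network
interactions always originate at the salience network.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .atlas import BLOCKS, EdgeVector, TNMEdgeMask, devectorize, vectorize

__all__ = [
    "BlockSignificance",
    "StrengthProfile",
    "CircuitSummary",
    "to_matrix",
    "block_contributions",
    "null_block_significance",
    "signed_strength",
    "top_regions",
    "circuit_summary",
]


def _edge_values(w, mask: TNMEdgeMask | None) -> tuple[np.ndarray, TNMEdgeMask]:
    if isinstance(w, EdgeVector):
        return w.values, w.mask
    w = np.asarray(w, dtype=float)
    if mask is None:
        raise ValueError("mask required")
    if w.ndim == 2:
        return vectorize(w, mask).values, mask
    if w.shape[0] != mask.n_edges:
        raise ValueError("edge vector length does not match mask")
    return w, mask


def to_matrix(wc, mask: TNMEdgeMask | None = None) -> np.ndarray:
    """Symmetric coefficient matrix: zeros off-mask and on the diagonal."""
    values, mask = _edge_values(wc, mask)
    return devectorize(values, mask)


def block_contributions(W, mask: TNMEdgeMask | None = None) -> dict[str, float]:
    """Per-block sum of |coefficient| over unique (upper-triangle) edges."""
    values, mask = _edge_values(W, mask)
    a = np.abs(values)
    return {b: float(a[mask.block_edges(b)].sum()) for b in BLOCKS}


@dataclass
class BlockSignificance:
    """Permutation test of the five TNM blocks' total contributions."""

    observed: dict[str, float]
    null_percentile_value: dict[str, float]
    significant: dict[str, bool]
    n_perm: int
    percentile: float
    seed: int | None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "block": list(BLOCKS),
                "observed": [self.observed[b] for b in BLOCKS],
                "null_percentile_value": [self.null_percentile_value[b] for b in BLOCKS],
                "significant": [self.significant[b] for b in BLOCKS],
            }
        )


def null_block_significance(
    wc,
    mask: TNMEdgeMask | None = None,
    n_perm: int = 1000,
    percentile: float = 99.0,
    seed=None,
) -> BlockSignificance:
    """Test block contributions against uniformly shuffled coefficients.

    Every permutation rearranges the full coefficient vector (zeros
    included) over the allowed edge positions; a block is significant iff
    its observed contribution strictly exceeds the given percentile
    (linear interpolation) of its own null ensemble.

    Seed policy: permutations are the row-wise argsort order of an
    (n_perm, E) uniform draw from ``numpy.random.default_rng(seed)``.
    """
    values, mask = _edge_values(wc, mask)
    if values.size == 0:
        raise ValueError("empty coefficient vector")
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is small; percentile estimates will be coarse",
                      stacklevel=2)
    rng = np.random.default_rng(seed)
    observed = block_contributions(values, mask)
    a = np.abs(values)
    E = a.size
    order = np.argsort(rng.random((n_perm, E)), axis=1)
    block_id = np.empty(E, dtype=np.int64)
    for bi, b in enumerate(BLOCKS):
        block_id[mask.block_edges(b)] = bi
    # permuted vector w'[pos] = a[order[pos]]; accumulate per block via bincount
    flat = (np.arange(n_perm)[:, None] * len(BLOCKS) + block_id[None, :]).ravel()
    null_sums = np.bincount(
        flat, weights=a[order].ravel(), minlength=n_perm * len(BLOCKS)
    ).reshape(n_perm, len(BLOCKS))
    null_q, signif = {}, {}
    for bi, b in enumerate(BLOCKS):
        q = float(np.percentile(null_sums[:, bi], percentile, method="linear"))
        null_q[b] = q
        signif[b] = bool(observed[b] > q)
    return BlockSignificance(observed, null_q, signif, n_perm, percentile, seed)


@dataclass
class StrengthProfile:
    """Per-region positive and negative strengths of a coefficient matrix."""

    positive: np.ndarray   # >= 0, per region
    negative: np.ndarray   # <= 0, per region
    networks: np.ndarray   # TNM class per region ("" when unknown)
    region_names: list[str] | None = None

    @property
    def n_regions(self) -> int:
        return self.positive.size

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "region": self.region_names
                if self.region_names is not None
                else list(range(self.n_regions)),
                "network": self.networks,
                "positive_strength": self.positive,
                "negative_strength": self.negative,
            }
        )
        return df


def signed_strength(W, mask: TNMEdgeMask | None = None, region_table=None) -> StrengthProfile:
    """Positive/negative row sums of the symmetric coefficient matrix."""
    if isinstance(W, EdgeVector) or np.asarray(W).ndim == 1:
        W = to_matrix(W, mask)
    W = np.asarray(W, dtype=float)
    pos = np.where(W > 0, W, 0.0).sum(axis=1)
    neg = np.where(W < 0, W, 0.0).sum(axis=1)
    if region_table is not None:
        networks = region_table.tnm_classes
        names = region_table.names
    else:
        networks = np.array([""] * W.shape[0], dtype=object)
        names = None
    return StrengthProfile(pos, neg, networks, names)


def top_regions(profile: StrengthProfile, fraction: float = 0.05) -> pd.DataFrame:
    """Top contributing signed-strength entries.

    The R positive and R negative strengths are pooled (2R entries),
    ranked by absolute value, and the top ceil(fraction * 2R) entries are
    selected; the reported threshold is the corresponding percentile of
    the pooled |strength| distribution.
    """
    if not (0 < fraction < 1):
        raise ValueError("fraction must lie in (0, 1)")
    R = profile.n_regions
    entries = []
    for r in range(R):
        entries.append((r, "positive", profile.positive[r]))
        entries.append((r, "negative", profile.negative[r]))
    df = pd.DataFrame(entries, columns=["region_id", "sign", "strength"])
    df["abs_strength"] = df["strength"].abs()
    n_select = int(np.ceil(fraction * 2 * R))
    df = df.sort_values(
        ["abs_strength", "region_id", "sign"], ascending=[False, True, True],
        kind="stable",
    ).reset_index(drop=True)
    sel = df.head(n_select).copy()
    sel["network"] = [profile.networks[r] for r in sel["region_id"]]
    if profile.region_names is not None:
        sel["region"] = [profile.region_names[r] for r in sel["region_id"]]
    threshold = float(np.percentile(df["abs_strength"], 100 * (1 - fraction)))
    sel.attrs["threshold"] = threshold
    return sel


@dataclass
class CircuitEntry:
    block: str
    endpoints: tuple[str, ...]
    direction: str | None  # "SN->FPN" / "SN->DMN" for between-network, else None
    sign: str              # "increased" | "decreased" | "mixed"
    observed: float
    null_percentile_value: float


@dataclass
class CircuitSummary:
    """Directed-circuit reading of the significant blocks.

    Sign comes from the fitted coefficients (signed block sum);
    directionality for between-network blocks is imposed by the TNM's
    top-down assumption (SN is always the origin).  FPN–DMN never appears
    because the edge mask excludes that block.
    """

    entries: list[CircuitEntry]

    def to_dicts(self) -> list[dict]:
        return [
            {
                "block": e.block,
                "endpoints": list(e.endpoints),
                "direction": e.direction,
                "sign": e.sign,
                "observed": e.observed,
                "null_p": e.null_percentile_value,
            }
            for e in self.entries
        ]

    def __iter__(self):
        return iter(self.entries)

    def __len__(self):
        return len(self.entries)


def circuit_summary(wc, mask: TNMEdgeMask | None, sig: BlockSignificance) -> CircuitSummary:
    """Summarize significant blocks as signed, TNM-directed interactions."""
    values, mask = _edge_values(wc, mask)
    entries = []
    for b in BLOCKS:
        if not sig.significant[b]:
            continue
        s = float(values[mask.block_edges(b)].sum())
        if s > 0:
            sign = "increased"
        elif s < 0:
            sign = "decreased"
        else:
            warnings.warn(f"block {b} has an exactly zero signed sum", stacklevel=2)
            sign = "mixed"
        nets = tuple(b.split("-"))
        direction = f"{nets[0]}->{nets[1]}" if nets[0] != nets[1] else None
        entries.append(
            CircuitEntry(b, nets, direction, sign, sig.observed[b],
                         sig.null_percentile_value[b])
        )
    return CircuitSummary(entries)
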
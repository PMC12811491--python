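"""Region bookkeeping for the triple-network connectivity domain.

The analysis operates on a cortical parcellation whose parcels carry
17-network labels (Schaefer/Yeo-style names such as
``17Networks_LH_ContA_PFCl_1``).  Three resting-state systems form the
triple network model (TNM): the salience network (SN), the frontoparietal
control network (FPN) and the default mode network (DMN).  All other
parcels are excluded, and — following the TNM's assumption that the SN
mediates communication between FPN and DMN — direct FPN–DMN edges are
removed from the connectivity domain.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "RegionTable",
    "FunctionalConnectome",
    "TNMEdgeMask",
    "EdgeVector",
    "BLOCKS",
    "TNM_NETWORK_MAP",
    "load_region_table",
    "assign_tnm_membership",
    "compute_connectome",
    "build_edge_mask",
    "vectorize",
    "devectorize",
]

#: 17-network subnetworks entering each TNM system.
TNM_NETWORK_MAP = {
    "SalVentAttnA": "SN",
    "SalVentAttnB": "SN",
    "ContA": "FPN",
    "ContB": "FPN",
    "ContC": "FPN",
    "DefaultA": "DMN",
    "DefaultB": "DMN",
    "DefaultC": "DMN",
}

#: Non-TNM 17-network labels that are silently excluded (plus common
#: subcortical naming); anything else is excluded with a warning.
KNOWN_EXCLUDED = {
    "VisCent", "VisPeri", "SomMotA", "SomMotB",
    "DorsAttnA", "DorsAttnB", "LimbicA", "LimbicB",
    "TempPar", "Subcortical",
}

#: The five edge blocks the TNM admits, in canonical order.
BLOCKS = ("SN-SN", "FPN-FPN", "DMN-DMN", "SN-FPN", "SN-DMN")

_NAME_RE = re.compile(r"17Networks_(LH|RH)_([A-Za-z]+)")


@dataclass(frozen=True)
class RegionRecord:
    region_id: int
    name: str
    network17: str
    hemisphere: str
    tnm_class: str = "EXCLUDED"


class RegionTable:
    """Ordered parcel lookup; file order is canonical for all matrices."""

    def __init__(self, records: list[RegionRecord]):
        ids = [r.region_id for r in records]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate region id")
        if ids != list(range(len(ids))):
            raise ValueError("region ids must be contiguous and 0-based in file order")
        self.records = list(records)

    @property
    def n_regions(self) -> int:
        return len(self.records)

    @property
    def tnm_classes(self) -> np.ndarray:
        return np.array([r.tnm_class for r in self.records], dtype=object)

    @property
    def names(self) -> list[str]:
        return [r.name for r in self.records]

    def network_counts(self) -> dict[str, int]:
        counts = {"SN": 0, "FPN": 0, "DMN": 0, "EXCLUDED": 0}
        for r in self.records:
            counts[r.tnm_class] += 1
        return counts

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": [r.region_id for r in self.records],
                "name": [r.name for r in self.records],
                "network17": [r.network17 for r in self.records],
                "hemisphere": [r.hemisphere for r in self.records],
                "tnm_class": [r.tnm_class for r in self.records],
            }
        )

    def __len__(self) -> int:
        return self.n_regions

    def __repr__(self) -> str:
        c = self.network_counts()
        return (
            f"RegionTable(n={self.n_regions}, SN={c['SN']}, FPN={c['FPN']}, "
            f"DMN={c['DMN']}, excluded={c['EXCLUDED']})"
        )


def _parse_name(name: str) -> tuple[str, str]:
    m = _NAME_RE.search(name)
    if m is None:
        raise ValueError(f"cannot parse network/hemisphere from region name {name!r}")
    return m.group(2), m.group(1)


def load_region_table(path: str | Path) -> RegionTable:
    """Read a delimited (comma or tab) parcel lookup.

    Columns ``id`` and ``name`` are required; ``network17`` and
    ``hemisphere`` are parsed from Schaefer-style names when absent.
    TNM membership is assigned on load.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    if df.empty:
        raise ValueError(f"empty region table: {path}")
    cols = {c.lower(): c for c in df.columns}
    if "id" not in cols or "name" not in cols:
        raise ValueError("region table requires 'id' and 'name' columns")
    ids = df[cols["id"]].astype(int).tolist()
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate region id")
    names = df[cols["name"]].astype(str).tolist()
    records = []
    for i, (rid, name) in enumerate(zip(ids, names)):
        if "network17" in cols and "hemisphere" in cols:
            net = str(df[cols["network17"]].iloc[i])
            hemi = str(df[cols["hemisphere"]].iloc[i])
        else:
            net, hemi = _parse_name(name)
        records.append(RegionRecord(rid, name, net, hemi))
    table = RegionTable(records)
    return assign_tnm_membership(table)


def assign_tnm_membership(table: RegionTable) -> RegionTable:
    """Map 17-network labels onto {SN, FPN, DMN, EXCLUDED}.

    SN = SalVentAttn A/B, FPN = Cont A/B/C, DMN = Default A/B/C; every
    other label (visual, somatomotor, dorsal attention, limbic,
    temporo-parietal, subcortical) is excluded.  Labels outside the known
    vocabulary are excluded with a warning rather than rejected.
    """
    records = []
    for r in table.records:
        cls = TNM_NETWORK_MAP.get(r.network17)
        if cls is None:
            if r.network17 not in KNOWN_EXCLUDED:
                warnings.warn(
                    f"unknown network label {r.network17!r} for region "
                    f"{r.name!r}; excluding from the TNM domain",
                    stacklevel=2,
                )
            cls = "EXCLUDED"
        records.append(RegionRecord(r.region_id, r.name, r.network17, r.hemisphere, cls))
    return RegionTable(records)


@dataclass
class FunctionalConnectome:
    """One participant's region-by-region Pearson correlation matrix."""

    participant_id: str
    matrix: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("connectome must be a square matrix")
        if not np.all(np.abs(m - m.T) <= 1e-12):
            raise ValueError(
                f"connectome for {self.participant_id!r} is not symmetric within 1e-12"
            )
        if not np.allclose(np.diag(m), 1.0, rtol=0, atol=1e-12):
            raise ValueError(f"connectome for {self.participant_id!r} lacks a unit diagonal")
        off = m[~np.eye(m.shape[0], dtype=bool)]
        if off.size and (off.min() < -1 - 1e-12 or off.max() > 1 + 1e-12):
            raise ValueError("off-diagonal couplings must lie in [-1, 1]")
        self.matrix = m

    @property
    def n_regions(self) -> int:
        return self.matrix.shape[0]


def compute_connectome(timeseries: np.ndarray, participant_id: str) -> FunctionalConnectome:
    """Pairwise Pearson correlations of regional time series.

    ``timeseries`` is T×n_regions (rows = time points, columns = regions
    in :class:`RegionTable` order).
    """
    ts = np.asarray(timeseries, dtype=float)
    if ts.ndim != 2:
        raise ValueError("time series must be a 2-D (T x n_regions) matrix")
    if ts.shape[0] < 3:
        raise ValueError(f"need at least 3 time points, got {ts.shape[0]}")
    sd = ts.std(axis=0)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        raise ValueError(f"zero temporal variance in region(s) {dead.tolist()}")
    r = np.corrcoef(ts, rowvar=False)
    np.clip(r, -1.0, 1.0, out=r)
    r = (r + r.T) / 2.0
    np.fill_diagonal(r, 1.0)
    return FunctionalConnectome(participant_id, r)


class TNMEdgeMask:
    """Allowed region pairs of the TNM connectivity domain.

    Pairs are ordered row-major over the upper triangle (i < j) restricted
    to edges within SN, within FPN, within DMN, and between SN–FPN and
    SN–DMN.  The FPN–DMN block and every pair touching an excluded region
    are absent.
    """

    def __init__(self, pairs: np.ndarray, block_labels: np.ndarray, n_regions: int):
        self.pairs = np.asarray(pairs, dtype=int)
        self.block_labels = np.asarray(block_labels, dtype=object)
        self.n_regions = int(n_regions)
        if self.pairs.shape != (len(self.block_labels), 2):
            raise ValueError("pairs and block labels disagree")
        self._block_index = {
            b: np.flatnonzero(self.block_labels == b) for b in BLOCKS
        }

    @property
    def n_edges(self) -> int:
        return self.pairs.shape[0]

    def block_edges(self, block: str) -> np.ndarray:
        """Edge-vector positions belonging to one of the five blocks."""
        return self._block_index[block]

    def __len__(self) -> int:
        return self.n_edges

    def __repr__(self) -> str:
        sizes = {b: len(ix) for b, ix in self._block_index.items()}
        return f"TNMEdgeMask(E={self.n_edges}, blocks={sizes})"


@dataclass
class EdgeVector:
    """Length-E vector of one participant's TNM edge couplings."""

    values: np.ndarray
    mask: TNMEdgeMask

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.values.shape[0] != self.mask.n_edges:
            raise ValueError(
                f"edge vector length {self.values.shape[0]} does not match "
                f"mask E={self.mask.n_edges}"
            )


def _block_label(a: str, b: str) -> str:
    if a == b:
        return f"{a}-{a}"
    # between-network blocks are always written SN-first
    other = b if a == "SN" else a
    return f"SN-{other}"


def build_edge_mask(table: RegionTable) -> TNMEdgeMask:
    """Enumerate the TNM-allowed edges of a region table.

    E = sum_k C(n_k, 2) + n_SN*n_FPN + n_SN*n_DMN over the three network
    sizes; FPN–DMN pairs are excluded by construction.
    """
    classes = table.tnm_classes
    counts = table.network_counts()
    for net in ("SN", "FPN", "DMN"):
        if counts[net] == 0:
            raise ValueError(f"TNM class {net} has no regions")
    n = table.n_regions
    iu, ju = np.triu_indices(n, k=1)
    ci, cj = classes[iu], classes[ju]
    keep = (ci != "EXCLUDED") & (cj != "EXCLUDED")
    keep &= ~(((ci == "FPN") & (cj == "DMN")) | ((ci == "DMN") & (cj == "FPN")))
    iu, ju, ci, cj = iu[keep], ju[keep], ci[keep], cj[keep]
    labels = np.array([_block_label(a, b) for a, b in zip(ci, cj)], dtype=object)
    return TNMEdgeMask(np.column_stack([iu, ju]), labels, n)


def vectorize(fc: FunctionalConnectome | np.ndarray, mask: TNMEdgeMask) -> EdgeVector:
    """Extract the masked upper-triangle entries in mask order."""
    m = fc.matrix if isinstance(fc, FunctionalConnectome) else np.asarray(fc, dtype=float)
    if m.shape[0] < mask.n_regions:
        raise ValueError(
            f"matrix has {m.shape[0]} regions but mask indexes up to {mask.n_regions}"
        )
    return EdgeVector(m[mask.pairs[:, 0], mask.pairs[:, 1]], mask)


def devectorize(v: EdgeVector | np.ndarray, mask: TNMEdgeMask | None = None) -> np.ndarray:
    """Embed an edge vector as a symmetric matrix, zero off-mask and on the diagonal."""
    if isinstance(v, EdgeVector):
        mask = v.mask
        values = v.values
    else:
        if mask is None:
            raise ValueError("mask required when passing a bare array")
        values = np.asarray(v, dtype=float).ravel()
        if values.shape[0] != mask.n_edges:
            raise ValueError("edge vector length does not match mask")
    out = np.zeros((mask.n_regions, mask.n_regions))
    out[mask.pairs[:, 0], mask.pairs[:, 1]] = values
    out[mask.pairs[:, 1], mask.pairs[:, 0]] = values
    return out
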
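"""Atlas bookkeeping: ROI -> network assignment and network-pair enumeration.

The analysis is phrased at the level of *functional network pairs*: ordered
pairs (target network, source network) of named brain systems.  Because the
connectivity model is directed (each region is modeled as a weighted sum of
all the others), the pair (A, B) — weights with the modeled region in A and
the predictor region in B — is distinct from (B, A), and a network of n
regions has n*(n-1) within-network connections.

The default schema mirrors the Gordon cortical parcellation: 333 regions of
interest, 12 named networks, and 47 regions not assigned to any network.
Only network membership matters to this pipeline, so the schema is purely a
labeling; no surface geometry is represented.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

UNASSIGNED = "UNASSIGNED"

#: Number of ROIs per network in the Gordon-style default schema.
GORDON_NETWORK_SIZES = {
    "Aud": 24,
    "CiO": 40,
    "CiP": 5,
    "Def": 41,
    "DoA": 32,
    "FrP": 24,
    "ReT": 8,
    "SMl": 38,
    "SMm": 8,
    "Sal": 4,
    "VeA": 23,
    "Vis": 39,
}
GORDON_N_ROIS = 333

#: The six higher-order networks retained for the network-pair statistics
#: (primary sensory/motor and unimodal systems are excluded).
DEFAULT_INCLUDED_NETWORKS = ("CiP", "Def", "DoA", "FrP", "Sal", "VeA")


@dataclass(frozen=True)
class ParcellationSchema:
    """ROI ids with network assignments.

    Parameters
    ----------
    roi_ids
        ROI identifiers in matrix-row order (file ids, typically 1-based;
        row/column *indices* in all matrices are the 0-based positions in
        this list).
    network_of
        Mapping ROI id -> network name; unassigned ROIs map to
        ``UNASSIGNED``.
    """

    roi_ids: tuple[int, ...]
    network_of: dict[int, str] = field(hash=False)

    def __post_init__(self):
        if len(set(self.roi_ids)) != len(self.roi_ids):
            raise ValueError("duplicate roi_id in parcellation")
        if len(self.roi_ids) == 0:
            raise ValueError("empty parcellation")
        missing = [r for r in self.roi_ids if r not in self.network_of]
        if missing:
            raise ValueError(f"ROIs without network entry: {missing[:5]}")

    @property
    def n_rois(self) -> int:
        return len(self.roi_ids)

    @property
    def network_names(self) -> tuple[str, ...]:
        """Named networks in order of first appearance (UNASSIGNED excluded)."""
        seen: list[str] = []
        for rid in self.roi_ids:
            name = self.network_of[rid]
            if name != UNASSIGNED and name not in seen:
                seen.append(name)
        return tuple(seen)

    @property
    def n_unassigned(self) -> int:
        return sum(1 for r in self.roi_ids if self.network_of[r] == UNASSIGNED)

    def indices_of(self, network: str) -> np.ndarray:
        """0-based matrix indices of the ROIs belonging to ``network``."""
        if network != UNASSIGNED and network not in self.network_names:
            raise KeyError(f"unknown network: {network!r}")
        return np.array(
            [i for i, r in enumerate(self.roi_ids) if self.network_of[r] == network],
            dtype=np.intp,
        )

    def network_size(self, network: str) -> int:
        return len(self.indices_of(network))

    def included_indices(self, networks) -> np.ndarray:
        """Concatenated indices of several networks (order of the given list)."""
        return np.concatenate([self.indices_of(n) for n in networks])

    def to_frame(self) -> pd.DataFrame:
        """Label table (roi_id, network) suitable for round-tripping."""
        return pd.DataFrame(
            {"roi_id": list(self.roi_ids),
             "network": [self.network_of[r] for r in self.roi_ids]}
        )


@dataclass(frozen=True)
class NetworkPair:
    """Directed network pair: weights with target in one network, source in other.

    ``connections`` lists (target index, source index) matrix positions in a
    deterministic order (target-major within the pair); self-connections are
    never included.
    """

    target_network: str
    source_network: str
    connections: tuple[tuple[int, int], ...] = field(hash=False)

    @property
    def name(self) -> str:
        return f"{self.target_network} and {self.source_network}"

    @property
    def n_connections(self) -> int:
        return len(self.connections)


def load_parcellation(path) -> ParcellationSchema:
    """Read a tab-separated label table with columns ``roi_id`` and ``network``.

    Blank or missing network strings map to ``UNASSIGNED``.  Duplicate ROI
    ids and empty tables raise ``ValueError``.
    """
    try:
        table = pd.read_csv(path, sep="\t", dtype={"roi_id": int, "network": str})
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"empty parcellation table: {path}") from exc
    for col in ("roi_id", "network"):
        if col not in table.columns:
            raise ValueError(f"label table must have a {col!r} column")
    if len(table) == 0:
        raise ValueError(f"empty parcellation table: {path}")
    if table["roi_id"].duplicated().any():
        dupes = table.loc[table["roi_id"].duplicated(), "roi_id"].tolist()
        raise ValueError(f"duplicate roi_id values: {dupes[:5]}")
    networks = table["network"].fillna(UNASSIGNED).str.strip()
    networks = networks.where(networks != "", UNASSIGNED)
    return ParcellationSchema(
        roi_ids=tuple(int(r) for r in table["roi_id"]),
        network_of=dict(zip(table["roi_id"].astype(int), networks)),
    )


def _schema_from_sizes(sizes: dict[str, int], n_total: int) -> ParcellationSchema:
    ids, network_of = [], {}
    rid = 1
    for name, n in sizes.items():
        for _ in range(n):
            ids.append(rid)
            network_of[rid] = name
            rid += 1
    while rid <= n_total:
        ids.append(rid)
        network_of[rid] = UNASSIGNED
        rid += 1
    return ParcellationSchema(roi_ids=tuple(ids), network_of=network_of)


def gordon_schema() -> ParcellationSchema:
    """Gordon-style default: 333 ROIs, 12 networks, 47 unassigned.

    Which particular ROI carries which id is immaterial to the pipeline
    (only network membership is used), so ids are assigned in contiguous
    blocks per network, unassigned ROIs last.
    """
    return _schema_from_sizes(GORDON_NETWORK_SIZES, GORDON_N_ROIS)


def small_schema() -> ParcellationSchema:
    """Reduced analogue of the default schema for simulation studies.

    Keeps the same network names and their size ordering but shrinks every
    network, so full-cohort simulations (type-I error, power) run at desk
    scale.  40 ROIs: six included networks totalling 30 ROIs, a 4-ROI Vis
    network, and 6 unassigned ROIs.
    """
    sizes = {"CiP": 3, "Def": 8, "DoA": 6, "FrP": 5, "Sal": 3, "VeA": 5, "Vis": 4}
    return _schema_from_sizes(sizes, 40)


def enumerate_pairs(schema: ParcellationSchema, networks) -> list[NetworkPair]:
    """All k^2 ordered network pairs over ``networks``, self-pairs included.

    The order matches the conventional pair listing: the source network is
    the outer loop, the target network the inner one, each over the given
    network list — i.e. the first block is every "X and N1" pair, and so on.
    """
    networks = list(networks)
    for n in networks:
        if n not in schema.network_names:
            raise KeyError(f"unknown network: {n!r}")
    pairs = []
    for source in networks:
        for target in networks:
            t_idx = schema.indices_of(target)
            s_idx = schema.indices_of(source)
            conns = tuple(
                (int(t), int(s)) for t in t_idx for s in s_idx if t != s
            )
            pairs.append(NetworkPair(target, source, conns))
    return pairs


def count_connections(pair: NetworkPair) -> int:
    """Number of directed connections grouped under the pair."""
    return pair.n_connections


def extract_pair_values(matrix: np.ndarray, pair: NetworkPair, n_rois: int | None = None) -> np.ndarray:
    """Vector of matrix values at the pair's connections, in pair order.

    ``matrix`` is indexed (target, source); its diagonal is never touched
    because self-connections are excluded from every pair.
    """
    matrix = np.asarray(matrix)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {matrix.shape}")
    if n_rois is not None and matrix.shape[0] != n_rois:
        raise ValueError(
            f"matrix dimension {matrix.shape[0]} does not match schema size {n_rois}"
        )
    idx = np.asarray(pair.connections, dtype=np.intp)
    if idx.size and idx.max() >= matrix.shape[0]:
        raise ValueError("pair indices exceed matrix dimension")
    if not idx.size:
        return np.empty(0, dtype=matrix.dtype)
    return matrix[idx[:, 0], idx[:, 1]]


def connection_count_table(schema: ParcellationSchema, networks=DEFAULT_INCLUDED_NETWORKS) -> pd.DataFrame:
    """Per-pair connection counts plus a total row (tab-separated on export)."""
    pairs = enumerate_pairs(schema, networks)
    rows = [{"name": p.name, "n_connections": p.n_connections} for p in pairs]
    total = sum(r["n_connections"] for r in rows)
    rows.append({"name": "Total", "n_connections": total})
    return pd.DataFrame(rows)
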
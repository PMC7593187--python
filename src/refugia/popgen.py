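"""Mitochondrial haplotype diversity and population differentiation.

This module turns an aligned set of COI sequences, each tagged with the
mountain region it was sampled in, into the standard population-genetic
summaries used in phylogeographic studies of range-restricted species:

* haplotype collapsing (exact sequence identity after column filtering),
* per-region and overall diversity — number of haplotypes ``Hn``, number of
  region-unique haplotypes ``Hu``, Nei's sample-size-corrected haplotype
  diversity ``Hd`` and nucleotide diversity ``pi``,
* a two-level AMOVA giving the phi-statistic (proportion of molecular
  variance among regions) with a label-permutation null,
* a minimum-spanning haplotype network with edges annotated by the number
  of nucleotide substitutions.

Sequences are expected pre-aligned.  Columns containing anything outside
``{A, C, G, T}`` in any record are removed alignment-wide by default
("complete deletion"), so haplotype identity is well defined.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
from Bio import SeqIO

__all__ = [
    "Alignment",
    "HaplotypeTable",
    "DiversityStats",
    "AmovaResult",
    "HaplotypeNetwork",
    "crop_and_filter",
    "collapse_haplotypes",
    "diversity_stats",
    "diversity_table",
    "amova_phi",
    "build_network",
    "hamming_matrix",
]

_VALID = frozenset(b"ACGT")


@dataclass(frozen=True)
class Alignment:
    """An aligned, region-annotated sequence set.

    Rows are individuals; every sequence has the same length.  Characters
    are uppercase ``A/C/G/T/N/-``.
    """

    sample_ids: tuple[str, ...]
    region_ids: tuple[str, ...]
    sequences: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.sequences:
            raise ValueError("alignment has no records")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise ValueError(f"sequences have unequal lengths: {sorted(lengths)}")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample_ids are not unique")
        if not (len(self.sample_ids) == len(self.region_ids) == len(self.sequences)):
            raise ValueError("sample_ids, region_ids and sequences differ in length")

    @property
    def n(self) -> int:
        return len(self.sequences)

    @property
    def length(self) -> int:
        return len(self.sequences[0])

    @property
    def regions(self) -> tuple[str, ...]:
        """Region labels in order of first appearance."""
        seen: dict[str, None] = {}
        for r in self.region_ids:
            seen.setdefault(r)
        return tuple(seen)

    def to_matrix(self) -> np.ndarray:
        """Byte matrix of shape (n, length), one row per record."""
        return np.frombuffer(
            "".join(self.sequences).encode("ascii"), dtype=np.uint8
        ).reshape(self.n, self.length)

    @classmethod
    def from_fasta(cls, fasta_path: str | Path, region_csv: str | Path) -> "Alignment":
        """Read a FASTA alignment plus a ``sample_id,region_id`` CSV map."""
        region_of: dict[str, str] = {}
        with open(region_csv, newline="") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None or {
                "sample_id",
                "region_id",
            } - set(reader.fieldnames):
                raise ValueError("region CSV must have header sample_id,region_id")
            for row in reader:
                region_of[row["sample_id"]] = row["region_id"]
        ids, regions, seqs = [], [], []
        for rec in SeqIO.parse(str(fasta_path), "fasta"):
            if rec.id not in region_of:
                raise ValueError(f"sample {rec.id!r} missing from region map")
            ids.append(rec.id)
            regions.append(region_of[rec.id])
            seqs.append(str(rec.seq).upper())
        return cls(tuple(ids), tuple(regions), tuple(seqs))


def crop_and_filter(
    alignment: Alignment, policy: str = "drop-ambiguous-columns"
) -> Alignment:
    """Remove alignment columns that carry ambiguity codes or gaps.

    With the default policy every column containing any character outside
    ``{A,C,G,T}`` in any record is deleted alignment-wide, so two records
    are the same haplotype iff they are byte-identical afterwards.
    ``keep-all`` returns the alignment unchanged.
    """
    if policy not in ("drop-ambiguous-columns", "keep-all"):
        raise ValueError(f"unknown column policy {policy!r}")
    if policy == "keep-all":
        return alignment
    mat = alignment.to_matrix()
    valid = np.isin(mat, np.frombuffer(b"ACGT", dtype=np.uint8))
    keep = valid.all(axis=0)
    if not keep.any():
        raise ValueError("alignment collapsed to zero length")
    kept = mat[:, keep]
    seqs = tuple(row.tobytes().decode("ascii") for row in kept)
    return Alignment(alignment.sample_ids, alignment.region_ids, seqs)


@dataclass(frozen=True)
class HaplotypeTable:
    """Collapsed haplotypes with per-region copy counts.

    ``hap_ids`` start at 1 and follow order of first appearance in the
    alignment.  ``counts[i][region]`` is the number of individuals of
    haplotype ``i+1`` sampled in ``region``.
    """

    sequences: tuple[str, ...]
    counts: tuple[Mapping[str, int], ...]
    total_n: int

    @property
    def n_haplotypes(self) -> int:
        return len(self.sequences)

    @property
    def hap_ids(self) -> tuple[int, ...]:
        return tuple(range(1, len(self.sequences) + 1))

    @property
    def regions(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for c in self.counts:
            for r in c:
                seen.setdefault(r)
        return tuple(seen)

    def frequency(self, hap_id: int) -> int:
        """Total copy count of one haplotype across all regions."""
        return sum(self.counts[hap_id - 1].values())

    def region_counts(self, scope: str) -> np.ndarray:
        """Copy counts per haplotype within one region, or overall for 'All'."""
        if scope == "All":
            return np.array([self.frequency(h) for h in self.hap_ids])
        return np.array([c.get(scope, 0) for c in self.counts])

    def unique_to(self, region: str) -> list[int]:
        """Haplotype ids whose every copy was sampled in ``region``."""
        out = []
        for h in self.hap_ids:
            c = self.counts[h - 1]
            if c.get(region, 0) > 0 and all(v == 0 for r, v in c.items() if r != region):
                out.append(h)
        return out

    def to_frame(self):
        """Long-format table ``hap_id,sequence,region,count`` (pandas)."""
        import pandas as pd

        rows = [
            {"hap_id": h, "sequence": self.sequences[h - 1], "region": r, "count": c}
            for h in self.hap_ids
            for r, c in self.counts[h - 1].items()
            if c > 0
        ]
        return pd.DataFrame(rows, columns=["hap_id", "sequence", "region", "count"])


def collapse_haplotypes(alignment: Alignment) -> HaplotypeTable:
    """Group records by exact sequence identity.

    The alignment must already be filtered to pure ``A/C/G/T`` columns;
    ids are assigned in order of first appearance.
    """
    mat = alignment.to_matrix()
    if not np.isin(mat, np.frombuffer(b"ACGT", dtype=np.uint8)).all():
        raise ValueError("alignment contains ambiguous characters; filter first")
    index: dict[str, int] = {}
    counts: list[dict[str, int]] = []
    regions = alignment.regions
    for seq, region in zip(alignment.sequences, alignment.region_ids):
        if seq not in index:
            index[seq] = len(index)
            counts.append({r: 0 for r in regions})
        counts[index[seq]][region] += 1
    return HaplotypeTable(
        sequences=tuple(index),
        counts=tuple(counts),
        total_n=alignment.n,
    )


def hamming_matrix(sequences: Sequence[str]) -> np.ndarray:
    """Pairwise Hamming distance (site mismatch count) between sequences."""
    mat = np.frombuffer("".join(sequences).encode("ascii"), dtype=np.uint8).reshape(
        len(sequences), -1
    )
    return (mat[:, None, :] != mat[None, :, :]).sum(axis=2)


@dataclass(frozen=True)
class DiversityStats:
    """One row of a regional diversity table.

    Attributes
    ----------
    scope : region id, or ``"All"`` for the pooled sample.
    n : number of sequences in scope.
    hn : number of distinct haplotypes.
    hu : haplotypes found in no other region (for ``"All"``: haplotypes
        confined to a single region).
    hd : haplotype diversity, the sample-size-corrected probability that
        two randomly drawn sequences differ: ``n (1 - sum p_i^2) / (n-1)``.
    pi : nucleotide diversity, mean pairwise per-site difference.
    """

    scope: str
    n: int
    hn: int
    hu: int
    hd: float
    pi: float


def diversity_stats(
    table: HaplotypeTable, alignment: Alignment, scope: str = "All"
) -> DiversityStats:
    """Compute Hn, Hu, Hd and pi for one region or the pooled sample."""
    if scope != "All" and scope not in table.regions:
        raise ValueError(f"unknown scope {scope!r}")
    counts = table.region_counts(scope)
    n = int(counts.sum())
    present = counts > 0
    hn = int(present.sum())
    if scope == "All":
        hu = sum(len(table.unique_to(r)) for r in table.regions)
    else:
        hu = len(table.unique_to(scope))
    if n < 2:
        warnings.warn(
            f"scope {scope!r} has n={n}; Hd and pi reported as 0", stacklevel=2
        )
        return DiversityStats(scope, n, hn, hu, 0.0, 0.0)
    p = counts / n
    hd = n * (1.0 - float(p @ p)) / (n - 1)
    # pi from haplotype distances weighted by copy counts; within-haplotype
    # pairs contribute zero.
    idx = np.flatnonzero(present)
    d = hamming_matrix([table.sequences[i] for i in idx])
    c = counts[idx].astype(float)
    pair_diffs = 0.5 * float(c @ d @ c)  # sum over ordered pairs / 2
    n_pairs = n * (n - 1) / 2
    L = len(table.sequences[0])
    pi = pair_diffs / (n_pairs * L)
    return DiversityStats(scope, n, hn, hu, hd, pi)


def diversity_table(table: HaplotypeTable, alignment: Alignment):
    """Regional diversity summary (one row per region plus 'All') as a DataFrame."""
    import pandas as pd

    scopes = ["All", *table.regions]
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for s in scopes:
            st = diversity_stats(table, alignment, s)
            rows.append(
                {
                    "region": st.scope,
                    "n": st.n,
                    "Hn": st.hn,
                    "Hu": st.hu,
                    "Hd": st.hd,
                    "pi": st.pi,
                }
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class AmovaResult:
    """Two-level AMOVA decomposition and permutation test."""

    phi: float
    ss_among: float
    ss_within: float
    variance_among: float
    variance_within: float
    p_value: float
    n_permutations: int


def _phi_components(d2: np.ndarray, labels: np.ndarray) -> tuple[float, float, float, float]:
    """Variance components from squared distances and group labels.

    Returns (ss_among, ss_within, var_among, var_within) using the
    standard sum-of-squared-distances identity: the SS of a set equals the
    sum of squared pairwise distances divided by the set size.
    """
    N = len(labels)
    groups = np.unique(labels)
    G = len(groups)
    ss_total = d2.sum() / (2.0 * N)  # full matrix counts each pair twice
    ss_within = 0.0
    sizes = np.empty(G)
    for k, g in enumerate(groups):
        m = labels == g
        sizes[k] = m.sum()
        if sizes[k] > 0:
            ss_within += d2[np.ix_(m, m)].sum() / (2.0 * sizes[k])
    ss_among = ss_total - ss_within
    df_among = G - 1
    df_within = N - G
    ms_within = ss_within / df_within if df_within > 0 else 0.0
    n0 = (N - (sizes**2).sum() / N) / df_among  # unbiased size coefficient
    ms_among = ss_among / df_among
    var_within = ms_within
    var_among = (ms_among - ms_within) / n0
    return ss_among, ss_within, var_among, var_within


def _phi(var_among: float, var_within: float) -> float:
    total = var_among + var_within
    if total <= 0:
        return 0.0
    return var_among / total


def amova_phi(
    alignment: Alignment,
    groups: Mapping[str, str] | None = None,
    n_permutations: int = 999,
    seed: int | None = None,
) -> AmovaResult:
    """AMOVA phi-statistic over groups of sequences, with a permutation null.

    By default each mountain region is one group.  Distances are pairwise
    Hamming counts on the retained sites; the null is built by permuting
    individuals across groups with group sizes held fixed, and the p-value
    carries the +1 correction: ``p = (#{perm phi >= observed} + 1)/(B + 1)``.
    """
    if groups is None:
        labels = np.array(alignment.region_ids)
    else:
        labels = np.array([groups[s] for s in alignment.sample_ids])
    if len(np.unique(labels)) < 2:
        raise ValueError("AMOVA needs at least 2 groups")
    d = hamming_matrix(alignment.sequences).astype(float)
    d2 = d**2
    ss_a, ss_w, va, vw = _phi_components(d2, labels)
    observed = _phi(va, vw)
    rng = np.random.default_rng(seed)
    exceed = 0
    perm = labels.copy()
    for _ in range(n_permutations):
        rng.shuffle(perm)
        _, _, pva, pvw = _phi_components(d2, perm)
        if _phi(pva, pvw) >= observed:
            exceed += 1
    p = (exceed + 1) / (n_permutations + 1)
    return AmovaResult(observed, ss_a, ss_w, va, vw, p, n_permutations)


@dataclass
class HaplotypeNetwork:
    """Minimum-spanning haplotype network.

    ``graph`` is an undirected networkx graph whose nodes are hap_ids with
    a ``frequency`` attribute and whose edges carry ``substitutions``.
    """

    graph: nx.Graph
    connection_limit: int | None = None

    @property
    def edges(self) -> list[tuple[int, int, int]]:
        return sorted(
            (min(a, b), max(a, b), int(d["substitutions"]))
            for a, b, d in self.graph.edges(data=True)
        )

    def write_edgelist_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["hap_a", "hap_b", "substitutions"])
            w.writerows(self.edges)

    def write_gml(self, path: str | Path) -> None:
        nx.write_gml(self.graph, str(path))


def build_network(
    table: HaplotypeTable, connection_limit: int | str | None = None
) -> HaplotypeNetwork:
    """Build the minimum-spanning network over haplotypes.

    A minimum spanning tree on pairwise Hamming distances is augmented with
    every non-tree edge whose weight ties the longest edge on the tree path
    between its endpoints (so equally parsimonious alternative connections
    are retained), then edges longer than ``connection_limit`` are dropped.
    ``connection_limit`` of ``None`` or ``"none"`` keeps all network edges.
    """
    if connection_limit == "none":
        connection_limit = None
    if connection_limit is not None and connection_limit < 1:
        raise ValueError("connection_limit must be >= 1")
    d = hamming_matrix(table.sequences)
    k = table.n_haplotypes
    g = nx.Graph()
    for h in table.hap_ids:
        g.add_node(h, frequency=table.frequency(h))
    if k == 1:
        return HaplotypeNetwork(g, connection_limit)
    complete = nx.Graph()
    for i in range(k):
        for j in range(i + 1, k):
            complete.add_edge(i + 1, j + 1, weight=int(d[i, j]))
    mst = nx.minimum_spanning_tree(complete)
    for a, b, data in mst.edges(data=True):
        g.add_edge(a, b, substitutions=int(data["weight"]))
    # tie retention: add non-tree edges matching the bottleneck of the
    # cycle they would close
    for i in range(k):
        for j in range(i + 1, k):
            a, b = i + 1, j + 1
            if g.has_edge(a, b):
                continue
            path = nx.shortest_path(mst, a, b)
            bottleneck = max(
                mst[u][v]["weight"] for u, v in zip(path[:-1], path[1:])
            )
            if int(d[i, j]) == bottleneck:
                g.add_edge(a, b, substitutions=int(d[i, j]))
    if connection_limit is not None:
        drop = [
            (a, b)
            for a, b, w in g.edges(data="substitutions")
            if w > connection_limit
        ]
        g.remove_edges_from(drop)
    return HaplotypeNetwork(g, connection_limit)
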
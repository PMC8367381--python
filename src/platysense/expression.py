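"""Cluster-level expression quantification for de novo transcriptomes.

De novo assemblies represent one gene by several partially redundant
transcripts (splice variants, allelic polymorphisms, fragmented contigs).
This module groups transcripts that share exact sequence overlap into
clusters ("genes"), assigns each cluster a nominal length equal to the
length of the union of its unique sequence, and converts read counts per
cluster into length- and depth-normalized expression values (TPM-style:
counts per kilobase of nominal length per million reads in the sample).

The overlap rule is exact-match: two transcripts overlap when they share
an identical substring of at least ``min_overlap`` base pairs, on either
strand by default. ``N`` bases never match.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "TranscriptRecord",
    "GeneCluster",
    "CountTable",
    "read_fasta",
    "write_fasta",
    "filter_transcripts",
    "cluster_transcripts",
    "nominal_length",
    "build_gene_clusters",
    "compute_expression",
    "is_expressed",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class TranscriptRecord:
    """A single assembled transcript: an id and a nucleotide sequence."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("transcript id must be non-empty")
        if not self.sequence:
            raise ValueError(f"transcript {self.id!r} has an empty sequence")
        seq = self.sequence.upper()
        if set(seq) - set("ACGTN"):
            bad = sorted(set(seq) - set("ACGTN"))
            raise ValueError(f"transcript {self.id!r} contains invalid bases {bad}")
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class GeneCluster:
    """A set of transcripts grouped by sequence overlap; the unit of counting.

    ``nominal_length_bp`` is the length of the non-redundant sequence of the
    cluster (longest member plus the uncovered parts of the others); it is
    ``None`` until computed.
    """

    cluster_id: str
    member_ids: frozenset[str]
    nominal_length_bp: int | None = None

    def __post_init__(self) -> None:
        if not self.member_ids:
            raise ValueError("cluster must have at least one member")
        self.member_ids = frozenset(self.member_ids)


@dataclass
class CountTable:
    """Read counts per (gene cluster, sample).

    ``counts`` is a genes x samples DataFrame of nonnegative integers.
    Library size per sample is the column sum — the total number of reads
    counted in that sample.
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("counts must be nonnegative")

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    @classmethod
    def from_tsv(cls, path) -> "CountTable":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(counts=df)

    def to_tsv(self, path) -> None:
        self.counts.to_csv(path, sep="\t", index_label="gene")


def read_fasta(path) -> list[TranscriptRecord]:
    """Read a multi-FASTA file into transcript records."""
    return [
        TranscriptRecord(id=rec.id, sequence=str(rec.seq))
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(records: Iterable[TranscriptRecord], path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records),
        str(path),
        "fasta",
    )


def filter_transcripts(
    transcripts: Sequence[TranscriptRecord], min_len: int = 250
) -> list[TranscriptRecord]:
    """Keep transcripts of length >= ``min_len`` bp, preserving order."""
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    return [t for t in transcripts if len(t) >= min_len]


def _kmers(seq: str, k: int, strand_agnostic: bool) -> set[str]:
    """Canonical k-mer set of ``seq``; k-mers containing N are excluded."""
    out: set[str] = set()
    for i in range(len(seq) - k + 1):
        km = seq[i : i + k]
        if "N" in km:
            continue
        if strand_agnostic:
            rc = _revcomp(km)
            km = km if km <= rc else rc
        out.add(km)
    return out


class _UnionFind:
    def __init__(self, items: Iterable[str]) -> None:
        self._parent = {x: x for x in items}

    def find(self, x: str) -> str:
        p = self._parent
        root = x
        while p[root] != root:
            root = p[root]
        while p[x] != root:  # path compression
            p[x], x = root, p[x]
        return root

    def union(self, a: str, b: str) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self._parent[rb] = ra

    def groups(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for x in self._parent:
            out.setdefault(self.find(x), set()).add(x)
        return out


def cluster_transcripts(
    transcripts: Sequence[TranscriptRecord],
    min_overlap: int = 50,
    strand_agnostic: bool = True,
) -> list[GeneCluster]:
    """Partition transcripts into clusters by chained exact overlap.

    Two transcripts end up in one cluster iff they are connected through a
    chain of pairwise shared exact substrings of length >= ``min_overlap``.
    Sharing a substring of length >= k is equivalent to sharing at least one
    exact k-mer, so the partition is computed from a k-mer index plus
    union-find closure.  Cluster ids are derived from the lexicographically
    smallest member id, so the result is invariant to input order.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    ids = [t.id for t in transcripts]
    if len(set(ids)) != len(ids):
        raise ValueError("transcript ids must be unique")
    uf = _UnionFind(ids)
    seen: dict[str, str] = {}  # k-mer -> first transcript id carrying it
    for t in transcripts:
        for km in _kmers(t.sequence, min_overlap, strand_agnostic):
            other = seen.setdefault(km, t.id)
            if other != t.id:
                uf.union(other, t.id)
    clusters = []
    for members in uf.groups().values():
        cid = "cl_" + min(members)
        clusters.append(GeneCluster(cluster_id=cid, member_ids=frozenset(members)))
    clusters.sort(key=lambda c: c.cluster_id)
    return clusters


def _ascii(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _match_intervals(a: str, b: str, k: int) -> list[tuple[int, int]]:
    """Half-open intervals on ``a`` covered by exact matches to ``b`` of length >= k.

    Scans every alignment diagonal of the (a, b) comparison and records
    maximal runs of identical bases (N never matches) of length >= k.
    """
    A, B = _ascii(a), _ascii(b)
    n, m = len(A), len(B)
    if n == 0 or m == 0 or min(n, m) < k:
        return []
    out: list[tuple[int, int]] = []
    N = ord("N")
    for d in range(-(m - 1), n):  # diagonal: a[i] vs b[i - d]
        lo_a = max(d, 0)
        hi_a = min(n, m + d)
        if hi_a - lo_a < k:
            continue
        sa = A[lo_a:hi_a]
        sb = B[lo_a - d : hi_a - d]
        eq = (sa == sb) & (sa != N)
        if not eq.any():
            continue
        # maximal run boundaries
        padded = np.concatenate(([False], eq, [False]))
        diff = np.diff(padded.astype(np.int8))
        starts = np.nonzero(diff == 1)[0]
        ends = np.nonzero(diff == -1)[0]
        for s, e in zip(starts, ends):
            if e - s >= k:
                out.append((lo_a + int(s), lo_a + int(e)))
    return out


def _merge_intervals(ivals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not ivals:
        return []
    ivals = sorted(ivals)
    merged = [list(ivals[0])]
    for s, e in ivals[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def nominal_length(
    cluster_members: Sequence[TranscriptRecord],
    min_overlap: int = 50,
    strand_agnostic: bool = True,
) -> int:
    """Length of the non-redundant concatenated sequence of one cluster.

    The longest member seeds the concatenate; every other member, in
    decreasing length order (ties broken by id), contributes only the parts
    not covered by an exact match of >= ``min_overlap`` bp against the
    concatenate built so far.  The result lies between the longest member
    length and the sum of member lengths.
    """
    if not cluster_members:
        raise ValueError("cluster must have at least one member")
    order = sorted(cluster_members, key=lambda t: (-len(t), t.id))
    segments: list[str] = [order[0].sequence]
    total = len(order[0])
    for member in order[1:]:
        ivals: list[tuple[int, int]] = []
        for seg in segments:
            ivals.extend(_match_intervals(member.sequence, seg, min_overlap))
            if strand_agnostic:
                ivals.extend(
                    _match_intervals(member.sequence, _revcomp(seg), min_overlap)
                )
        covered = _merge_intervals(ivals)
        pos = 0
        for s, e in covered:
            if s > pos:
                segments.append(member.sequence[pos:s])
                total += s - pos
            pos = max(pos, e)
        if pos < len(member):
            segments.append(member.sequence[pos:])
            total += len(member) - pos
    return total


def build_gene_clusters(
    transcripts: Sequence[TranscriptRecord],
    min_overlap: int = 50,
    min_len: int = 250,
    strand_agnostic: bool = True,
) -> list[GeneCluster]:
    """Filter, cluster and measure transcripts in one pass."""
    kept = filter_transcripts(transcripts, min_len=min_len)
    by_id = {t.id: t for t in kept}
    clusters = cluster_transcripts(kept, min_overlap=min_overlap, strand_agnostic=strand_agnostic)
    for cl in clusters:
        members = [by_id[i] for i in sorted(cl.member_ids)]
        cl.nominal_length_bp = nominal_length(
            members, min_overlap=min_overlap, strand_agnostic=strand_agnostic
        )
    return clusters


def compute_expression(
    counts: CountTable, lengths: Mapping[str, int]
) -> pd.DataFrame:
    """Normalize counts to nominal length (kb) and library depth (millions).

    E[g, s] = C[g, s] / (L_g / 1000) / (N_s / 10^6), with N_s the column sum
    of counts for sample s.
    """
    missing = [g for g in counts.genes if g not in lengths]
    if missing:
        raise KeyError(f"no nominal length for gene(s): {missing[:5]}")
    L = np.array([lengths[g] for g in counts.genes], dtype=float)
    if (L <= 0).any():
        raise ValueError("nominal lengths must be positive")
    N = counts.library_sizes.to_numpy(dtype=float)
    if (N <= 0).any():
        bad = [s for s, n in zip(counts.samples, N) if n <= 0]
        raise ValueError(f"sample(s) with zero library size: {bad}")
    values = counts.counts.to_numpy(dtype=float) / (L[:, None] / 1e3) / (N[None, :] / 1e6)
    return pd.DataFrame(values, index=counts.genes, columns=counts.samples)


def is_expressed(
    values: Sequence[float], threshold: float = 12.0, min_reps: int = 1
) -> bool:
    """True iff at least ``min_reps`` replicate values reach ``threshold``."""
    vals = np.asarray(values, dtype=float)
    if vals.size == 0:
        raise ValueError("is_expressed requires at least one replicate value")
    return int((vals >= threshold).sum()) >= min_reps
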
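"""Best-hit homology mapping and gene-set overlap permutation testing.

Queries from one species are mapped onto target-species genes by their best
BLAST hit under a stringent E-value threshold (many queries may share one
target; the map is single-valued per query).  Whether a particular query
gene set over-represents a target signature is assessed against a null of
size-matched random query sets drawn from the full query universe: the
empirical p-value is the frequency of null overlaps at least as large as
the observed one.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "OverlapResult",
    "read_blast_hits",
    "best_hit_map",
    "observed_overlap",
    "permutation_overlap_test",
]

# BLAST tabular (outfmt 6) default column layout
OUTFMT6_COLUMNS = (
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
)


@dataclass(frozen=True)
class OverlapResult:
    """Observed overlap, its resampling null, and the empirical p-value.

    ``p_value`` is n_geq / n_perm; when no permutation reaches the observed
    overlap (n_geq = 0) the p-value is reported as the bound 1 / n_perm with
    ``p_is_bound`` set.  ``n_gt`` / ``n_eq`` split n_geq into strictly-greater
    and tied permutations (needed for randomized-p calibration checks).
    """

    observed: int
    n_perm: int
    n_geq: int
    n_gt: int
    n_eq: int
    p_value: float
    p_is_bound: bool
    seed: int | None
    null_mean: float
    null_sd: float

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


def read_blast_hits(path) -> pd.DataFrame:
    """Read BLAST outfmt-6-style TSV; keeps qseqid, sseqid, evalue, bitscore.

    Accepts the full 12-column layout or any header-less TSV whose first two
    and last two columns follow the same convention.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] == len(OUTFMT6_COLUMNS):
        df.columns = OUTFMT6_COLUMNS
    elif df.shape[1] >= 4:
        cols = list(df.columns)
        df = df.rename(
            columns={cols[0]: "qseqid", cols[1]: "sseqid",
                     cols[-2]: "evalue", cols[-1]: "bitscore"}
        )
    else:
        raise ValueError(
            f"expected >= 4 tab-separated columns, found {df.shape[1]}"
        )
    out = df[["qseqid", "sseqid", "evalue", "bitscore"]].copy()
    for col in ("evalue", "bitscore"):
        vals = pd.to_numeric(out[col], errors="coerce")
        if vals.isna().any():
            row = int(vals.index[vals.isna()][0])
            raise ValueError(f"malformed {col} in hit row {row}")
        out[col] = vals
    if (out["evalue"] < 0).any():
        row = int(out.index[out["evalue"] < 0][0])
        raise ValueError(f"negative E-value in hit row {row}")
    return out


def best_hit_map(
    hits: pd.DataFrame, e_threshold: float = 1e-20
) -> dict[str, str]:
    """Map each query to the target of its best hit at E <= ``e_threshold``.

    Best = lowest E-value; ties broken by highest bit score, then by
    lexicographic target id.  Queries with no qualifying hit are absent.
    """
    qual = hits[hits["evalue"] <= e_threshold]
    if qual.empty:
        return {}
    ranked = qual.sort_values(
        ["qseqid", "evalue", "bitscore", "sseqid"],
        ascending=[True, True, False, True],
        kind="mergesort",
    )
    best = ranked.drop_duplicates("qseqid", keep="first")
    return dict(zip(best["qseqid"], best["sseqid"]))


def observed_overlap(
    query_set: Iterable[str],
    mapping: Mapping[str, str],
    signature: Iterable[str],
    count: str = "target",
) -> int:
    """Overlap between a query set's mapped homologs and a target signature.

    ``count="target"`` (default) counts distinct target genes hit;
    ``count="query"`` counts query genes whose homolog is in the signature.
    """
    sig = set(signature)
    if count == "target":
        targets = {mapping[q] for q in query_set if q in mapping}
        return len(targets & sig)
    if count == "query":
        return sum(1 for q in query_set if q in mapping and mapping[q] in sig)
    raise ValueError("count must be 'target' or 'query'")


def _null_overlaps(
    target_codes: np.ndarray,
    sig_mask: np.ndarray,
    set_size: int,
    n_perm: int,
    rng: np.random.Generator,
    count: str,
    batch: int = 2000,
) -> np.ndarray:
    """Overlap statistic for ``n_perm`` random query sets (vectorized).

    ``target_codes`` holds, per universe query, the integer code of its
    mapped target (-1 for unmapped); ``sig_mask`` flags signature targets.
    Sampling is uniform without replacement via random-key argpartition,
    done in batches to bound memory.
    """
    n_universe = target_codes.size
    out = np.empty(n_perm, dtype=np.int64)
    done = 0
    while done < n_perm:
        b = min(batch, n_perm - done)
        keys = rng.random((b, n_universe))
        idx = np.argpartition(keys, set_size - 1, axis=1)[:, :set_size]
        t = target_codes[idx]
        in_sig = (t >= 0) & sig_mask[np.clip(t, 0, None)]
        if count == "query":
            out[done : done + b] = in_sig.sum(axis=1)
        else:
            t_sorted = np.sort(np.where(in_sig, t, -1), axis=1)
            is_sig = t_sorted >= 0
            new = np.ones_like(is_sig)
            new[:, 1:] = t_sorted[:, 1:] != t_sorted[:, :-1]
            out[done : done + b] = (is_sig & new).sum(axis=1)
        done += b
    return out


def permutation_overlap_test(
    universe: Sequence[str],
    query_set: Iterable[str],
    mapping: Mapping[str, str],
    signature: Iterable[str],
    n_perm: int = 10_000,
    seed: int | None = None,
    count: str = "target",
) -> OverlapResult:
    """Test a query set's signature overlap against size-matched random sets.

    Each of ``n_perm`` permutations draws ``len(query_set)`` queries from
    ``universe`` uniformly without replacement, maps them through
    ``mapping`` and computes the same overlap statistic as the observed
    value.  The p-value is the frequency of null overlaps >= observed.
    """
    universe = list(dict.fromkeys(universe))
    query_set = set(query_set)
    if not query_set:
        raise ValueError("query set must be non-empty")
    stray = query_set - set(universe)
    if stray:
        raise ValueError(f"query set contains ids outside the universe: {sorted(stray)[:5]}")
    set_size = len(query_set)
    if set_size > len(universe):
        raise ValueError("set_size exceeds universe size")
    if n_perm < 1:
        raise ValueError("n_perm must be positive")

    sig = set(signature)
    observed = observed_overlap(query_set, mapping, sig, count=count)

    # integer encoding of the map for the vectorized null
    targets = sorted({mapping[q] for q in universe if q in mapping})
    t_index = {t: i for i, t in enumerate(targets)}
    target_codes = np.array(
        [t_index.get(mapping.get(q), -1) if q in mapping else -1 for q in universe],
        dtype=np.int64,
    )
    sig_mask = np.zeros(max(len(targets), 1), dtype=bool)
    for t in targets:
        if t in sig:
            sig_mask[t_index[t]] = True

    rng = np.random.default_rng(seed)
    null = _null_overlaps(target_codes, sig_mask, set_size, n_perm, rng, count)
    n_gt = int((null > observed).sum())
    n_eq = int((null == observed).sum())
    n_geq = n_gt + n_eq
    if n_geq > 0:
        p_value, bound = n_geq / n_perm, False
    else:
        p_value, bound = 1.0 / n_perm, True
    return OverlapResult(
        observed=observed,
        n_perm=n_perm,
        n_geq=n_geq,
        n_gt=n_gt,
        n_eq=n_eq,
        p_value=p_value,
        p_is_bound=bound,
        seed=seed,
        null_mean=float(null.mean()),
        null_sd=float(null.std(ddof=1)) if n_perm > 1 else 0.0,
    )
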
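"""Ground-truth synthetic inputs for every pipeline stage.

Each generator emulates the statistical structure its consuming stage
assumes — overlapping transcript clusters, negative-binomial count
experiments with planted enriched genes, many-to-one homology universes
with optional planted signature enrichment, four-parameter-logistic
luminescence responses derived from a pigment template at a known λ_max,
and keypoint tracks with scheduled sinusoidal undulation bouts — and
returns the generating truth alongside the data.  All generators are
deterministic given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .behavior import POINT_NAMES, KeypointTrack
from .expression import CountTable, TranscriptRecord, _kmers
from .homology import observed_overlap
from .spectral import ASSAY_WAVELENGTHS, four_param_logistic, govardovskii_template

__all__ = [
    "HomologyScenario",
    "gen_transcript_clusters",
    "gen_count_experiment",
    "gen_homology_universe",
    "gen_action_spectrum_data",
    "gen_tracks",
    "gen_behavior_groups",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode("ascii")


def gen_transcript_clusters(
    n_clusters: int,
    members_per_cluster: int,
    member_len: int = 400,
    overlap_len: int = 60,
    min_overlap: int = 50,
    seed: int | None = None,
    max_tries: int = 50,
) -> tuple[list[TranscriptRecord], dict[str, int]]:
    """Transcript chains with planted exact overlaps, plus the true partition.

    Each cluster is a chain: consecutive members share an exact
    ``overlap_len``-bp substring, so the whole chain collapses into one
    cluster under the >= ``min_overlap`` rule.  Sequences are rejected and
    redrawn until no ``min_overlap``-mer (canonical, either strand) is
    shared between clusters, so the returned partition is exact truth.
    """
    if overlap_len >= member_len:
        raise ValueError("overlap_len must be smaller than member_len")
    if overlap_len < min_overlap:
        raise ValueError("planted overlaps must reach the clustering threshold")
    rng = np.random.default_rng(seed)
    records: list[TranscriptRecord] = []
    truth: dict[str, int] = {}
    used_kmers: set[str] = set()
    for c in range(n_clusters):
        for attempt in range(max_tries):
            members = []
            seq = _random_seq(rng, member_len)
            members.append(seq)
            for _ in range(1, members_per_cluster):
                seq = seq[-overlap_len:] + _random_seq(rng, member_len - overlap_len)
                members.append(seq)
            cluster_kmers: set[str] = set()
            for s in members:
                cluster_kmers |= _kmers(s, min_overlap, strand_agnostic=True)
            if cluster_kmers & used_kmers:
                continue  # cross-cluster collision: redraw this cluster
            used_kmers |= cluster_kmers
            for m, s in enumerate(members):
                tid = f"tx_c{c:03d}_m{m:02d}"
                records.append(TranscriptRecord(id=tid, sequence=s))
                truth[tid] = c
            break
        else:
            raise RuntimeError(
                "could not draw a cluster without cross-cluster k-mer sharing; "
                "reduce n_clusters or member_len"
            )
    return records, truth


def gen_count_experiment(
    n_genes: int = 1000,
    n_replicates: int = 3,
    frac_enriched: float = 0.05,
    fold_change: float = 20.0,
    nb_dispersion: float = 0.1,
    lib_scale: float = 1.0,
    fdr_error_rate: float = 0.0,
    seed: int | None = None,
) -> tuple[CountTable, pd.DataFrame, set[str]]:
    """Negative-binomial count experiment with planted enriched genes.

    Three groups (sorted, unsorted_head, unsorted_trunk) x ``n_replicates``.
    Planted genes have a sorted-group mean ``fold_change`` times the shared
    background mean.  The emitted DE table carries truth-consistent FDRs
    (planted < 0.05, background > 0.05) with a configurable flip rate, and
    group means computed from depth-normalized expression of the generated
    counts.
    """
    if not 0.0 <= frac_enriched <= 1.0:
        raise ValueError("frac_enriched must lie in [0, 1]")
    if fold_change <= 1.0:
        raise ValueError("fold_change must exceed 1")
    rng = np.random.default_rng(seed)
    genes = [f"g{i:05d}" for i in range(n_genes)]
    n_planted = int(round(frac_enriched * n_genes))
    planted_idx = rng.choice(n_genes, size=n_planted, replace=False)
    planted = {genes[i] for i in planted_idx}

    base = rng.lognormal(mean=np.log(60.0), sigma=1.0, size=n_genes) + 20.0
    groups = ["sorted", "unsorted_head", "unsorted_trunk"]
    samples = [f"{g}_{r + 1}" for g in groups for r in range(n_replicates)]
    mu = np.tile(base[:, None], (1, len(samples))) * lib_scale
    mu[planted_idx, : n_replicates] *= fold_change  # sorted columns first
    size = 1.0 / nb_dispersion
    counts = rng.negative_binomial(size, size / (size + mu))
    df = pd.DataFrame(counts, index=genes, columns=samples)
    table = CountTable(counts=df)

    lib = df.sum(axis=0).to_numpy(dtype=float)
    cpm = df.to_numpy(dtype=float) / (lib[None, :] / 1e6)
    mean_sorted = cpm[:, :n_replicates].mean(axis=1)
    mean_head = cpm[:, n_replicates : 2 * n_replicates].mean(axis=1)
    mean_trunk = cpm[:, 2 * n_replicates :].mean(axis=1)

    is_planted = np.zeros(n_genes, dtype=bool)
    is_planted[planted_idx] = True
    flips = rng.random(n_genes) < fdr_error_rate
    sig = is_planted ^ flips
    fdr = np.where(
        sig,
        rng.uniform(1e-4, 0.049, size=n_genes),
        rng.uniform(0.051, 0.999, size=n_genes),
    )
    de = pd.DataFrame({
        "gene": genes,
        "mean_sorted": mean_sorted,
        "mean_unsorted_head": mean_head,
        "mean_unsorted_trunk": mean_trunk,
        "fdr": fdr,
    })
    return table, de, planted


@dataclass
class HomologyScenario:
    """A synthetic homology universe plus the truth needed to score it."""

    hits: pd.DataFrame  # outfmt-6-like columns: qseqid, sseqid, evalue, bitscore
    universe: list[str]
    query_set: set[str]
    signature: set[str]
    mapping: dict[str, str]
    true_overlap: int


def gen_homology_universe(
    n_query: int = 1000,
    n_target: int = 1000,
    mapped_frac: float = 1.0,
    injective: bool = True,
    signature_size: int = 100,
    planted_enrichment: float = 1.0,
    query_set_size: int = 50,
    decoy_rate: float = 0.3,
    seed: int | None = None,
) -> HomologyScenario:
    """Query->target homology universe with a query set of known enrichment.

    With ``planted_enrichment = 1`` the query set is a uniform draw (null
    scenario); larger values oversample queries whose homolog lies in the
    signature by that factor relative to the background rate.  Mapped pairs
    get E-values below 1e-20; decoy hits above the threshold are added at
    ``decoy_rate`` to exercise threshold filtering.
    """
    if signature_size > n_target:
        raise ValueError("signature_size cannot exceed n_target")
    if query_set_size > n_query:
        raise ValueError("query_set_size cannot exceed n_query")
    rng = np.random.default_rng(seed)
    queries = [f"q{i:05d}" for i in range(n_query)]
    targets = [f"t{i:05d}" for i in range(n_target)]
    n_mapped = int(round(mapped_frac * n_query))
    mapped_q = rng.choice(n_query, size=n_mapped, replace=False)
    if injective:
        if n_mapped > n_target:
            raise ValueError("injective map needs n_target >= mapped queries")
        mapped_t = rng.choice(n_target, size=n_mapped, replace=False)
    else:
        mapped_t = rng.integers(0, n_target, size=n_mapped)
    mapping = {queries[q]: targets[t] for q, t in zip(mapped_q, mapped_t)}
    signature = {targets[i] for i in rng.choice(n_target, size=signature_size, replace=False)}

    hitting = [q for q in queries if q in mapping and mapping[q] in signature]
    if planted_enrichment == 1.0:
        chosen = rng.choice(n_query, size=query_set_size, replace=False)
        query_set = {queries[i] for i in chosen}
    else:
        p0 = len(hitting) / n_query
        want = int(round(planted_enrichment * query_set_size * p0))
        if want > min(query_set_size, len(hitting)):
            raise ValueError("requested enrichment infeasible for these sizes")
        rest_pool = [q for q in queries if q not in set(hitting)]
        if query_set_size - want > len(rest_pool):
            raise ValueError("requested enrichment infeasible for these sizes")
        query_set = set(rng.choice(hitting, size=want, replace=False)) | set(
            rng.choice(rest_pool, size=query_set_size - want, replace=False)
        )

    rows = []
    for q in sorted(mapping):
        rows.append((q, mapping[q], 10.0 ** -rng.uniform(21, 150), rng.uniform(100, 500)))
        if rng.random() < decoy_rate:
            t = targets[rng.integers(0, n_target)]
            rows.append((q, t, 10.0 ** -rng.uniform(1, 19), rng.uniform(20, 90)))
    hits = pd.DataFrame(rows, columns=["qseqid", "sseqid", "evalue", "bitscore"])
    true_overlap = observed_overlap(query_set, mapping, signature)
    return HomologyScenario(
        hits=hits, universe=queries, query_set=query_set,
        signature=signature, mapping=mapping, true_overlap=true_overlap,
    )


def gen_action_spectrum_data(
    lambda_max: float,
    wavelengths: tuple[float, ...] = ASSAY_WAVELENGTHS,
    hill: float = 1.0,
    log_ec50_at_peak: float = 13.0,
    top: float = 500.0,
    baseline: float = 100.0,
    n_doses: int = 8,
    n_replicates: int = 3,
    noise_sd: float = 0.0,
    dose_halfspan: float = 2.0,
    seed: int | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Dose-response table generated from the pigment template at known λ_max.

    EC50(λ) = EC50_peak / template(λ, λ_max), so sensitivity falls off the
    template curve exactly.  Doses are ``n_doses`` log-spaced irradiances
    centered on each wavelength's true EC50 (± ``dose_halfspan`` decades);
    responses follow the 4PL plus optional Gaussian noise.
    """
    if not 400 <= lambda_max <= 550:
        raise ValueError("lambda_max must lie in the 400-550 nm scan range")
    rng = np.random.default_rng(seed)
    rows = []
    truth_ec50 = {}
    for wl in wavelengths:
        tmpl = govardovskii_template(float(wl), lambda_max)
        log_ec50 = log_ec50_at_peak - np.log10(tmpl)
        truth_ec50[float(wl)] = float(log_ec50)
        doses = np.linspace(log_ec50 - dose_halfspan, log_ec50 + dose_halfspan, n_doses)
        for rep in range(n_replicates):
            resp = four_param_logistic(doses, baseline, top, hill, log_ec50)
            if noise_sd > 0:
                resp = resp + rng.normal(0.0, noise_sd, size=resp.shape)
            for d, r in zip(doses, resp):
                rows.append((float(wl), float(d), rep + 1, float(r)))
    df = pd.DataFrame(rows, columns=["wavelength_nm", "log_irradiance", "replicate", "response"])
    truth = {
        "lambda_max": float(lambda_max),
        "hill": hill,
        "top": top,
        "baseline": baseline,
        "log_ec50": truth_ec50,
    }
    return df, truth


def _window_truth(
    n_windows: int, window_s: float, schedule: list[tuple[float, float, float, float]]
) -> tuple[np.ndarray, np.ndarray]:
    """(labels, boundary mask) per window given a bout schedule."""
    labels = np.zeros(n_windows, dtype=bool)
    boundary = np.zeros(n_windows, dtype=bool)
    for w in range(n_windows):
        w0, w1 = w * window_s, (w + 1) * window_s
        covered = 0.0
        for start, end, _, _ in schedule:
            covered += max(0.0, min(w1, end) - max(w0, start))
        if covered >= window_s - 1e-9:
            labels[w] = True
        elif covered > 1e-9:
            boundary[w] = True
            labels[w] = covered >= window_s / 2
    return labels, boundary


def gen_tracks(
    n_worms: int = 8,
    fps: float = 5.0,
    duration_s: float = 1800.0,
    bout_schedule: list[tuple[float, float, float, float]] | None = None,
    drift_px_per_s: float = 0.02,
    missing_rate: float | np.ndarray = 0.0,
    jitter_px: float = 0.05,
    genotype: str = "wildtype",
    t0_zt_hours: float = 6.0,
    worm_prefix: str = "worm",
    window_s: float = 10.0,
    seed: int | None = None,
) -> tuple[list[KeypointTrack], np.ndarray, np.ndarray]:
    """Keypoint tracks with scheduled sinusoidal undulation bouts.

    ``bout_schedule`` is a list of (start_s, end_s, freq_hz, amplitude_px);
    during a bout the five trunk points oscillate in y as
    amplitude * sin(2π f t + φ) with per-point, per-worm phases
    (peak-to-peak = 2 * amplitude).  Outside bouts points are quiescent
    apart from slow drift and sub-threshold jitter.  ``missing_rate`` may be
    a scalar or a per-point length-7 array.  Returns the tracks, per-window
    truth labels and a boundary mask flagging windows only partly covered
    by a bout (their labels follow majority coverage).
    """
    if bout_schedule is None:
        bout_schedule = []
    for _, _, f, _ in bout_schedule:
        if f >= fps / 2:
            raise ValueError("bout frequency must be below the Nyquist frequency")
    rng = np.random.default_rng(seed)
    n_frames = int(round(duration_s * fps))
    t = np.arange(n_frames) / fps
    rates = np.broadcast_to(np.asarray(missing_rate, dtype=float), (7,))
    tracks = []
    for w in range(n_worms):
        x = np.tile(30.0 * np.arange(7), (n_frames, 1)) + drift_px_per_s * t[:, None]
        y = np.full((n_frames, 7), 100.0) + drift_px_per_s * t[:, None]
        x += rng.normal(0.0, jitter_px, size=x.shape)
        y += rng.normal(0.0, jitter_px, size=y.shape)
        phases = rng.uniform(0.0, 2.0 * np.pi, size=5)
        for start, end, freq, amp in bout_schedule:
            mask = (t >= start) & (t < end)
            for j in range(5):  # body1..body5 occupy columns 1..5
                y[mask, 1 + j] += amp * np.sin(
                    2.0 * np.pi * freq * t[mask] + phases[j]
                )
        present = rng.random((n_frames, 7)) >= rates[None, :]
        tracks.append(
            KeypointTrack(
                worm_id=f"{worm_prefix}{w:03d}", genotype=genotype, fps=fps,
                x=x, y=y, present=present, t0_zt_hours=t0_zt_hours,
            )
        )
    n_windows = int(n_frames // round(window_s * fps))
    labels, boundary = _window_truth(n_windows, window_s, bout_schedule)
    return tracks, labels, boundary


def gen_behavior_groups(
    n_per_group: int = 16,
    ratio_a: float = 0.5,
    ratio_b: float = 0.2,
    fps: float = 5.0,
    duration_s: float = 1800.0,
    freq_hz: float = 1.0,
    amplitude_px: float = 2.0,
    window_s: float = 10.0,
    t0_zt_hours: float = 6.0,
    seed: int | None = None,
) -> dict[str, list[tuple[KeypointTrack, np.ndarray]]]:
    """Two genotype groups differing in expected undulation ratio.

    Per animal, each 10-s window independently hosts a full-window bout with
    probability ``ratio_a`` (wildtype) or ``ratio_b`` (mutant); bouts are
    window-aligned so truth labels are exact.  Returns genotype ->
    [(track, truth labels per window), ...].
    """
    rng = np.random.default_rng(seed)
    n_windows = int(round(duration_s / window_s))
    out: dict[str, list[tuple[KeypointTrack, np.ndarray]]] = {}
    for genotype, ratio in (("wildtype", ratio_a), ("mutant", ratio_b)):
        group = []
        for w in range(n_per_group):
            active = rng.random(n_windows) < ratio
            schedule = [
                (i * window_s, (i + 1) * window_s, freq_hz, amplitude_px)
                for i in np.nonzero(active)[0]
            ]
            tracks, labels, _ = gen_tracks(
                n_worms=1, fps=fps, duration_s=duration_s,
                bout_schedule=schedule, genotype=genotype,
                t0_zt_hours=t0_zt_hours,
                worm_prefix=f"{genotype}_{w:03d}_",
                window_s=window_s,
                seed=int(rng.integers(2**31)),
            )
            group.append((tracks[0], labels))
        out[genotype] = group
    return out
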
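"""Synthetic communities, multi-region read simulation, and reconstruction
scoring.

The simulator emulates the study conditions used to benchmark multi-region
profiling: communities of (by default) 100 reference sequences whose
rank-abundance follows a 1/x power law, a fixed total read budget (default
200,000) split equally across the amplified regions, and i.i.d. uniform
per-base substitution errors at a configurable rate.  Reconstructions are
scored by weighted recall (sum of simulated frequencies of exactly
recovered full-length sequences) and weighted precision (sum of
reconstructed frequencies placed on sequences truly present); even a single
mismatch over the full-length gene counts as an error.
"""

from __future__ import annotations

import string
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from ._seq import BASES, revcomp
from .read_processing import ReadTable
from .profiling_core import ProfileResult
from .reference_db import (
    PrimerPair,
    ReferenceSet,
    RefRecord,
    RegionKmerDb,
    compute_theoretical_groups,
)

DEFAULT_COMMUNITY_SIZE = 100
DEFAULT_TOTAL_READS = 200_000
DEFAULT_ERROR_RATE = 0.005


# ---------------------------------------------------------------------------
# communities
# ---------------------------------------------------------------------------

@dataclass
class SimulatedCommunity:
    """Member taxa (indices into a ReferenceSet) with rank frequencies."""

    taxon_indices: np.ndarray
    frequencies: np.ndarray
    seed: int | None = None

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, dtype=float)
        if not np.isclose(f.sum(), 1.0):
            raise ValueError("community frequencies must sum to 1")
        object.__setattr__(self, "frequencies", f)

    @property
    def n(self) -> int:
        return len(self.taxon_indices)

    def to_tsv(self, ref: ReferenceSet, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("taxon_id\tfrequency\n")
            for j, f in zip(self.taxon_indices, self.frequencies):
                fh.write(f"{ref.records[j].sequence_id}\t{f:.10g}\n")


def power_law_frequencies(n: int) -> np.ndarray:
    """Normalized 1/rank frequencies for ranks 1..n."""
    f = 1.0 / np.arange(1, n + 1)
    return f / f.sum()


def sample_power_law_community(
    ref: ReferenceSet, n: int = DEFAULT_COMMUNITY_SIZE, seed: int | None = None
) -> SimulatedCommunity:
    """Draw n distinct taxa uniformly; assign 1/rank frequencies.

    With n = 100 the lower-ranked half of the community carries a
    cumulative frequency of only ~13%, which is what makes such mixtures
    hard to profile.
    """
    if n > ref.J:
        raise ValueError(f"community size {n} exceeds reference size {ref.J}")
    rng = np.random.default_rng(seed)
    members = rng.choice(ref.J, size=n, replace=False)
    return SimulatedCommunity(members, power_law_frequencies(n), seed=seed)


def even_community(
    ref: ReferenceSet, taxon_indices: list[int] | np.ndarray
) -> SimulatedCommunity:
    """Equal-proportion community over the given taxa (mock-mixture style)."""
    idx = np.asarray(taxon_indices, dtype=int)
    return SimulatedCommunity(idx, np.full(len(idx), 1.0 / len(idx)))


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------

def _largest_remainder(weights: np.ndarray, total: int) -> np.ndarray:
    """Deterministic apportionment of `total` items proportional to weights."""
    exact = weights / weights.sum() * total
    base = np.floor(exact).astype(int)
    short = total - base.sum()
    if short:
        order = np.argsort(-(exact - base), kind="stable")
        base[order[:short]] += 1
    return base


def _mutate(seqs: list[str], counts: np.ndarray, rate: float,
            rng: np.random.Generator) -> dict[str, int]:
    """Expand (kmer, count) pairs into error-bearing reads, re-collapsed."""
    out: dict[str, int] = {}
    for seq, count in zip(seqs, counts):
        if count == 0:
            continue
        if rate == 0.0:
            out[seq] = out.get(seq, 0) + int(count)
            continue
        L = len(seq)
        codes = np.frombuffer(seq.encode(), dtype=np.uint8)
        base_idx = np.zeros(L, dtype=np.int8)
        for i, b in enumerate(BASES):
            base_idx[codes == ord(b)] = i
        reads = np.tile(base_idx, (int(count), 1))
        mask = rng.random(reads.shape) < rate
        shifts = rng.integers(1, 4, size=reads.shape)
        reads = np.where(mask, (reads + shifts) % 4, reads)
        uniq, cnt = np.unique(reads, axis=0, return_counts=True)
        for row, c in zip(uniq, cnt):
            s = "".join(BASES[i] for i in row)
            out[s] = out.get(s, 0) + int(c)
    return out


def simulate_region_reads(
    community: SimulatedCommunity,
    db: RegionKmerDb,
    total_reads: int = DEFAULT_TOTAL_READS,
    region_subset: list[int] | None = None,
    error_rate: float = DEFAULT_ERROR_RATE,
    seed: int | None = None,
    exact_proportions: bool = False,
) -> ReadTable:
    """Simulate a fixed total read budget split equally across regions.

    Within a region, reads are drawn multinomially from the community
    members amplified there (frequencies renormalized over those members —
    non-amplified taxa simply drop out of that region's PCR), emitting the
    member's region k-mer; each base is then substituted i.i.d. at
    ``error_rate`` to a uniformly chosen different base.  With
    ``exact_proportions`` the per-taxon read counts are apportioned
    deterministically instead of sampled, for noiseless ground-truth runs.
    Per-region totals always sum exactly to ``total_reads``.
    """
    regions = sorted(region_subset) if region_subset else list(db.region_ids)
    if not set(regions) <= set(db.region_ids):
        raise ValueError("region subset not contained in database regions")
    rng = np.random.default_rng(seed)
    per_region = np.full(len(regions), total_reads // len(regions))
    per_region[: total_reads % len(regions)] += 1

    table = ReadTable()
    for region, n_reads in zip(regions, per_region):
        present = [
            (int(j), f)
            for j, f in zip(community.taxon_indices, community.frequencies)
            if int(j) in db.taxon_kmers[region]
        ]
        if not present:
            table.regions[region] = []
            table.tally(f"region_{region}_no_amplified_member", int(n_reads))
            continue
        f = np.asarray([p[1] for p in present])
        f = f / f.sum()
        if exact_proportions:
            taxon_counts = _largest_remainder(f, int(n_reads))
        else:
            taxon_counts = rng.multinomial(int(n_reads), f)
        # one read sequence per (taxon, kmer); single-end picks ends 50/50
        seqs: list[str] = []
        counts: list[int] = []
        for (j, _), c in zip(present, taxon_counts):
            kmers = db.taxon_kmers[region][j]
            if len(kmers) == 1:
                seqs.append(kmers[0])
                counts.append(int(c))
            else:
                first = int(c) // 2 if exact_proportions else int(
                    rng.binomial(int(c), 0.5)
                )
                seqs.extend(kmers)
                counts.extend([first, int(c) - first])
        collapsed = _mutate(seqs, np.asarray(counts), error_rate, rng)
        table.regions[region] = sorted(
            collapsed.items(), key=lambda sc: (-sc[1], sc[0])
        )
    return table


def write_fastq(
    table: ReadTable,
    db: RegionKmerDb,
    path_r1: str | Path,
    path_r2: str | Path | None = None,
    barcode_len: int = 0,
    phred: int = 40,
    seed: int | None = None,
) -> None:
    """Write simulated reads as FASTQ with primers (and barcode) re-attached.

    Paired-end tables are split into R1 (forward primer + forward piece) and
    R2 (reverse primer + reverse piece), so the files round-trip through the
    read-preparation pipeline.  Qualities are uniform.
    """
    primers = {p.region_id: p for p in db.primers}
    rng = np.random.default_rng(seed)
    qual = chr(phred + 33)
    paired = db.mode == "paired" and path_r2 is not None
    fh1 = open(path_r1, "w")
    fh2 = open(path_r2, "w") if paired else None
    try:
        idx = 0
        for region in table.region_ids:
            p = primers[region]
            for seq, count in table.regions[region]:
                for _ in range(count):
                    barcode = "".join(
                        rng.choice(list(BASES), size=barcode_len)
                    ) if barcode_len else ""
                    if paired:
                        half = len(seq) // 2
                        r1 = barcode + p.forward + seq[:half]
                        r2 = barcode + p.reverse + seq[half:]
                        fh1.write(f"@sim_{idx}/1\n{r1}\n+\n{qual * len(r1)}\n")
                        fh2.write(f"@sim_{idx}/2\n{r2}\n+\n{qual * len(r2)}\n")
                    else:
                        r1 = barcode + p.forward + seq
                        fh1.write(f"@sim_{idx}\n{r1}\n+\n{qual * len(r1)}\n")
                    idx += 1
    finally:
        fh1.close()
        if fh2 is not None:
            fh2.close()


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

@dataclass
class EvaluationResult:
    """Weighted precision/recall of a reconstruction vs. the ground truth."""

    recall: float
    precision: float
    I_m: np.ndarray        # per simulated member: exactly recovered?
    I_r: np.ndarray        # per supported reconstructed taxon: truly present?
    n_reconstructed: int


def weighted_precision_recall(
    community: SimulatedCommunity, result: ProfileResult, ref: ReferenceSet
) -> EvaluationResult:
    """Exact full-length sequence comparison of truth vs. reconstruction.

    recall = sum_m f_m * I_m,  precision = sum_r x_r * I_r, with I set by
    perfect full-length matches only.
    """
    truth_seqs = {
        ref.records[int(j)].sequence: float(f)
        for j, f in zip(community.taxon_indices, community.frequencies)
    }
    id_to_seq = {r.sequence_id: r.sequence for r in ref.records}
    supported = result.supported()
    recon_seqs = [id_to_seq[result.taxon_ids[i]] for i in supported]
    recon_x = np.asarray([result.x[i] for i in supported])
    recon_set = set(recon_seqs)
    I_m = np.asarray(
        [1.0 if ref.records[int(j)].sequence in recon_set else 0.0
         for j in community.taxon_indices]
    )
    I_r = np.asarray([1.0 if s in truth_seqs else 0.0 for s in recon_seqs])
    recall = float((community.frequencies * I_m).sum())
    precision = float((recon_x * I_r).sum())
    return EvaluationResult(
        recall=recall, precision=precision, I_m=I_m, I_r=I_r,
        n_reconstructed=len(recon_seqs),
    )


# ---------------------------------------------------------------------------
# incremental region experiment
# ---------------------------------------------------------------------------

def greedy_region_ordering(db: RegionKmerDb) -> list[int]:
    """Order regions to maximize distinct footprint groups at every step.

    Greedily appends the region whose addition yields the most groups given
    the regions already chosen; ties break toward the smallest region id.
    Group counts along the ordering are non-decreasing, since adding a
    region can only split groups.
    """
    remaining = list(db.region_ids)
    chosen: list[int] = []
    while remaining:
        scored = [
            (compute_theoretical_groups(db, chosen + [r]).n_groups, -r, r)
            for r in remaining
        ]
        scored.sort(reverse=True)
        pick = scored[0][2]
        chosen.append(pick)
        remaining.remove(pick)
    return chosen


def incremental_region_experiment(
    ref: ReferenceSet,
    db: RegionKmerDb,
    community: SimulatedCommunity,
    total_reads: int = DEFAULT_TOTAL_READS,
    error_rate: float = DEFAULT_ERROR_RATE,
    seed: int | None = None,
    min_read_fraction: float = 1e-4,
    order: list[int] | None = None,
):
    """Reconstruct with 1, 2, ... regions (greedy order, constant read
    budget) and score each reconstruction.

    Returns a list of dict rows (n_regions, regions, precision, recall,
    mean_group_size) — the scaled analogue of benchmarking resolution
    against the number of amplified regions.
    """
    from .read_processing import apply_low_frequency_filter
    from .profiling_core import ErrorModel, profile

    order = order or greedy_region_ordering(db)
    rows = []
    for n_regions in range(1, len(order) + 1):
        subset = sorted(order[:n_regions])
        sub_db = db.subset(subset)
        reads = simulate_region_reads(
            community, sub_db, total_reads, subset, error_rate, seed
        )
        reads = apply_low_frequency_filter(reads, min_read_fraction)
        result = profile(reads, sub_db, ErrorModel(p_e=max(error_rate, 1e-3)))
        ev = weighted_precision_recall(community, result, ref)
        fp = compute_theoretical_groups(sub_db, subset)
        sizes = fp.group_size_of()
        member_sizes = [
            sizes[int(j)] for j in community.taxon_indices if int(j) in sizes
        ]
        rows.append(
            {
                "n_regions": n_regions,
                "regions": ",".join(map(str, subset)),
                "precision": ev.precision,
                "recall": ev.recall,
                "mean_member_group_size": float(np.mean(member_sizes))
                if member_sizes else float("nan"),
            }
        )
    return rows


# ---------------------------------------------------------------------------
# toy references (synthetic fixtures for tests, demos, and acceptance runs)
# ---------------------------------------------------------------------------

def toy_primer_set(n_regions: int = 3, seed: int = 7,
                   length: int = 18) -> list[PrimerPair]:
    """Random unambiguous primer pairs for synthetic references."""
    rng = np.random.default_rng(seed)
    pairs = []
    for r in range(1, n_regions + 1):
        fwd = "".join(rng.choice(list(BASES), size=length))
        rev = "".join(rng.choice(list(BASES), size=length))
        pairs.append(PrimerPair(r, fwd, rev))
    return pairs


def toy_reference(
    n_taxa: int,
    primers: list[PrimerPair],
    seed: int = 11,
    amplicon_len: int = 60,
    region_pool_sizes: dict[int, int] | None = None,
    pad: int = 10,
    n_species: int | None = None,
) -> ReferenceSet:
    """Synthetic full-length-style reference with embedded primer sites.

    Each sequence is pad + sum over regions of (forward primer + amplicon +
    reverse-complemented reverse primer + spacer).  ``region_pool_sizes``
    engineers shared amplicons: region r draws its amplicons from a pool of
    that size assigned round-robin, creating footprint groups; regions
    without an entry get a distinct amplicon per taxon.  Taxonomies carry
    synthetic species labels (``n_species`` distinct, default one per
    taxon).
    """
    rng = np.random.default_rng(seed)
    pool_sizes = region_pool_sizes or {}
    pools: dict[int, list[str]] = {}
    for p in primers:
        size = pool_sizes.get(p.region_id, n_taxa)
        pools[p.region_id] = [
            "".join(rng.choice(list(BASES), size=amplicon_len))
            for _ in range(size)
        ]
    n_species = n_species or n_taxa
    records = []
    letters = string.ascii_uppercase
    for j in range(n_taxa):
        parts = ["".join(rng.choice(list(BASES), size=pad))]
        for p in sorted(primers, key=lambda q: q.region_id):
            pool = pools[p.region_id]
            amp = pool[j % len(pool)]
            spacer = "".join(rng.choice(list(BASES), size=8))
            parts.append(p.forward + amp + revcomp(p.reverse) + spacer)
        seq = "".join(parts)
        species = j % n_species
        genus = letters[species % len(letters)]
        tax = (
            f"k__Bacteria;p__Toyphyla;c__Toyclass;o__Toyorder;"
            f"f__Toyfam;g__Genus{genus};s__species_{species:03d}"
        )
        records.append(RefRecord(f"toy{j:04d}", seq, tax, f"toy{j:04d}"))
    return ReferenceSet(records)
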
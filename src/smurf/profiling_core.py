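"""Probabilistic read matching and maximum-likelihood community estimation.

Each retained unique read i is matched against the k-mers of its region.
Under a constant per-base error probability p_e and independence across
positions, the probability of observing read i given k-mer h with n_e
mismatches over L compared bases is

    E_ih = (p_e/3)^n_e * (1 - p_e)^(L - n_e),

stored only where n_e <= the mismatch cap (default 2).  Combining with the
mixture matrix M gives Q_ij = sum_h E_ih M_hj, the probability of read i
given bacterium j.  The likelihood of the N matched reads,
prod_i sum_j Q_ij pi_j, is concave in the read-proportion vector pi on the
simplex, so the EM fixed-point update

    pi_j <- pi_j * (1/N) * sum_i Q_ij / (sum_j' Q_ij' pi_j')

converges to the global optimum.  Final frequencies are obtained by
normalizing pi_j by the number of amplified regions R_j (each taxon emits
R_j k-mers, so read share over-counts multi-region taxa):
x_j = (pi_j/R_j) / sum_j (pi_j/R_j).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from ._seq import encode, hamming_matrix
from .read_processing import ReadTable
from .reference_db import RegionKmerDb

EM_TOL = 1e-8
EM_MAX_ITER = 10_000
PI_PRUNE = 1e-12


@dataclass(frozen=True)
class ErrorModel:
    """Constant per-base substitution error model for read matching."""

    p_e: float = 0.005
    mismatch_cap: int = 2

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_e < 0.75:
            raise ValueError("p_e must be in [0, 0.75)")

    def probability(self, n_e: np.ndarray | int, L: int) -> np.ndarray | float:
        if self.p_e == 0.0:
            return np.where(np.asarray(n_e) == 0, 1.0, 0.0)
        return (self.p_e / 3.0) ** np.asarray(n_e, dtype=float) * (
            (1.0 - self.p_e) ** (L - np.asarray(n_e, dtype=float))
        )


@dataclass
class MatchMatrix:
    """Sparse read-vs-k-mer likelihood matrix over all regions.

    Rows are the retained unique reads that matched at least one k-mer;
    columns are the H k-mer rows of the database.
    """

    E: sp.csr_matrix                  # (n_reads, H)
    counts: np.ndarray                # (n_reads,) read multiplicities
    read_region: np.ndarray           # (n_reads,) region id per read
    read_seqs: list[str]
    n_unmatched: dict[int, int]       # region -> reads matching no k-mer
    matched_rows: set[int]            # k-mer rows hit by >= 1 read

    @property
    def n_reads(self) -> int:
        return self.E.shape[0]


def compute_read_kmer_probabilities(
    reads: ReadTable, db: RegionKmerDb, model: ErrorModel = ErrorModel()
) -> MatchMatrix:
    """Match every unique read to same-region k-mers within the mismatch cap.

    Reads matching no k-mer are excluded from the likelihood and tallied.
    Raises if a region's read length differs from its k-mer length.
    """
    L = db.read_length()
    rows_i: list[int] = []
    rows_h: list[int] = []
    vals: list[float] = []
    counts: list[int] = []
    regions: list[int] = []
    seqs: list[str] = []
    n_unmatched: dict[int, int] = {}
    matched_rows: set[int] = set()
    i_out = 0
    for region in reads.region_ids:
        entries = reads.regions[region]
        if not entries:
            continue
        if region not in db.taxon_kmers:
            raise ValueError(f"region {region} absent from the k-mer database")
        region_rows = db.region_rows(region)
        kmer_strs = [db.row_keys[h][1] for h in region_rows]
        bad = [len(s) for s, _ in entries if len(s) != L]
        if bad:
            raise ValueError(
                f"region {region}: read length {bad[0]} != database "
                f"read length {L}"
            )
        n_unmatched[region] = 0
        if not region_rows:
            n_unmatched[region] = len(entries)
            continue
        read_codes = np.stack([encode(s) for s, _ in entries])
        kmer_codes = np.stack([encode(s) for s in kmer_strs])
        mism = hamming_matrix(read_codes, kmer_codes)
        probs = model.probability(mism, L)
        within = mism <= model.mismatch_cap
        for local_i, (seq, count) in enumerate(entries):
            hit = np.nonzero(within[local_i])[0]
            if hit.size == 0:
                n_unmatched[region] += 1
                continue
            for local_h in hit:
                h = region_rows[local_h]
                rows_i.append(i_out)
                rows_h.append(h)
                vals.append(float(probs[local_i, local_h]))
                matched_rows.add(h)
            counts.append(count)
            regions.append(region)
            seqs.append(seq)
            i_out += 1
    E = sp.csr_matrix((vals, (rows_i, rows_h)), shape=(i_out, db.H))
    return MatchMatrix(
        E=E,
        counts=np.asarray(counts, dtype=float),
        read_region=np.asarray(regions, dtype=int),
        read_seqs=seqs,
        n_unmatched=n_unmatched,
        matched_rows=matched_rows,
    )


def filter_candidate_bacteria(
    db: RegionKmerDb, match: MatchMatrix
) -> np.ndarray:
    """Candidate taxa for reconstruction.

    A taxon is removed iff some region amplifies it with a perfect (zero
    mismatch) primer match yet none of its k-mers in that region was hit by
    any retained read — a perfectly amplifiable taxon that left no trace is
    implausible.  Taxa amplified only through mismatched primer sites are
    retained regardless of read support (the EM update zeroes unsupported
    taxa after one iteration in any case).
    """
    M_csc = db.M.tocsc()
    row_region = np.asarray([r for r, _ in db.row_keys])
    candidates = np.ones(db.J, dtype=bool)
    matched = np.zeros(db.H, dtype=bool)
    if match.matched_rows:
        matched[list(match.matched_rows)] = True
    for j in range(db.J):
        rows_j = M_csc.indices[M_csc.indptr[j]:M_csc.indptr[j + 1]]
        for region in db.perfect_primer_regions(j):
            in_region = rows_j[row_region[rows_j] == region]
            if in_region.size and not matched[in_region].any():
                candidates[j] = False
                break
    return np.nonzero(candidates)[0]


@dataclass
class LikelihoodState:
    """Final EM state: proportions, log-likelihood trace, convergence."""

    pi: np.ndarray
    log_likelihood: list[float]
    n_iter: int
    converged: bool
    N: float                         # total matched read count in the fit


def em_reconstruct(
    E: sp.csr_matrix,
    M: sp.spmatrix,
    counts: np.ndarray,
    tol: float = EM_TOL,
    max_iter: int = EM_MAX_ITER,
) -> LikelihoodState:
    """EM fixed-point estimation of read proportions pi over candidates.

    ``E`` is (n_reads, H), ``M`` is (H, n_candidates); each unique read's
    term is weighted by its count, which is mathematically identical to
    iterating over individual reads.  Reads whose Q row is entirely zero
    (they match only non-candidate taxa) are excluded from N.
    """
    if M.shape[1] < 1:
        raise ValueError("no candidate taxa")
    Q = (E @ M).tocsr()
    Q.eliminate_zeros()
    row_mass = np.asarray(Q.sum(axis=1)).ravel()
    live = row_mass > 0
    if not live.any():
        raise ValueError("no reads matched any candidate taxon")
    Q = Q[live]
    counts = np.asarray(counts, dtype=float)[live]
    N = counts.sum()
    n_cand = M.shape[1]
    pi = np.full(n_cand, 1.0 / n_cand)
    trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        p = Q @ pi                                    # per-read probability
        if not np.all(np.isfinite(p)) or (p <= 0).any():
            raise FloatingPointError(
                f"non-finite or zero read probability at iteration {it}"
            )
        trace.append(float(counts @ np.log(p)))
        pi_new = pi * (Q.T @ (counts / p)) / N
        delta = np.max(np.abs(pi_new - pi))
        pi = pi_new
        if delta < tol:
            converged = True
            break
    p = Q @ pi
    trace.append(float(counts @ np.log(p)))
    return LikelihoodState(
        pi=pi, log_likelihood=trace, n_iter=it, converged=converged, N=float(N)
    )


def normalize_frequencies(pi: np.ndarray, R: np.ndarray,
                          prune: float = PI_PRUNE) -> np.ndarray:
    """Convert read proportions to taxon frequencies: x_j ∝ pi_j / R_j."""
    pi = np.asarray(pi, dtype=float).copy()
    pi[pi < prune] = 0.0
    if not pi.any():
        raise ValueError("all proportions are zero")
    R = np.asarray(R, dtype=float)
    if np.any((pi > 0) & (R < 1)):
        raise ValueError("supported taxon with zero amplified regions")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(pi > 0, pi / R, 0.0)
    return ratio / ratio.sum()


@dataclass
class ProfileResult:
    """Reconstructed community: candidate taxa with pi, x, and support."""

    taxon_indices: np.ndarray        # indices into the database taxa
    taxon_ids: list[str]
    taxonomies: list[str]
    pi: np.ndarray
    x: np.ndarray
    R: np.ndarray
    n_iter: int
    converged: bool
    log_likelihood: list[float] = field(default_factory=list)
    region_read_counts: dict[int, int] = field(default_factory=dict)

    def supported(self) -> np.ndarray:
        """Positions (into the candidate arrays) with nonzero frequency."""
        return np.nonzero(self.x > 0)[0]

    def to_tsv(self, path) -> None:
        order = np.argsort(-self.x)
        with open(path, "w") as fh:
            fh.write("taxon_id\ttaxonomy\tpi\tx\tR\n")
            for i in order:
                fh.write(
                    f"{self.taxon_ids[i]}\t{self.taxonomies[i]}\t"
                    f"{self.pi[i]:.10g}\t{self.x[i]:.10g}\t{int(self.R[i])}\n"
                )


def profile(
    reads: ReadTable,
    db: RegionKmerDb,
    model: ErrorModel = ErrorModel(),
    tol: float = EM_TOL,
    max_iter: int = EM_MAX_ITER,
) -> ProfileResult:
    """Match reads, select candidates, run EM, and normalize frequencies."""
    match = compute_read_kmer_probabilities(reads, db, model)
    if match.n_reads == 0:
        raise ValueError("no reads matched the k-mer database")
    cand = filter_candidate_bacteria(db, match)
    # restrict to taxa with >= 1 matched k-mer: zero-support taxa receive
    # pi = 0 after one EM iteration, so this prunes without changing the fit
    matched = np.zeros(db.H, dtype=bool)
    matched[list(match.matched_rows)] = True
    M_csc = db.M.tocsc()
    has_support = np.asarray([
        matched[M_csc.indices[M_csc.indptr[j]:M_csc.indptr[j + 1]]].any()
        for j in range(db.J)
    ])
    cand = cand[has_support[cand]]
    if cand.size == 0:
        raise ValueError("candidate filter removed every taxon")
    state = em_reconstruct(
        match.E, db.M.tocsc()[:, cand], match.counts, tol=tol, max_iter=max_iter
    )
    x = normalize_frequencies(state.pi, db.R[cand])
    return ProfileResult(
        taxon_indices=cand,
        taxon_ids=[db.taxon_ids[j] for j in cand],
        taxonomies=[db.taxonomies[j] for j in cand],
        pi=state.pi,
        x=x,
        R=db.R[cand],
        n_iter=state.n_iter,
        converged=state.converged,
        log_likelihood=state.log_likelihood,
        region_read_counts={r: reads.n(r) for r in reads.region_ids},
    )
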
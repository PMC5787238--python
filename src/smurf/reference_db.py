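"""Reference 16S database handling: ambiguity expansion, in-silico PCR, and
the per-region k-mer database.

The profiling model represents every reference sequence ("bacterium" j) by
the read-length k-mers it would produce from each PCR-amplified region.  For
paired-end sequencing a (taxon, region) pair contributes a single k-mer — the
first k bases of the amplicon concatenated with the first k bases of its
reverse complement — with mixture weight M_hj = 1/R_j, where R_j is the
number of regions amplified for taxon j.  For single-end sequencing the two
k-length pieces are separate rows with M_hj = 0.5/R_j.  Columns of M for
amplified taxa therefore sum to one.
"""

from __future__ import annotations

import gzip
import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.sparse as sp
from Bio import SeqIO

from ._seq import IUPAC_SETS, encode, iupac_match_table, revcomp

MAX_AMBIGUOUS_POSITIONS = 3
PRIMER_MISMATCH_CAP = 2

_DB_FORMAT_VERSION = 1


# ---------------------------------------------------------------------------
# ambiguity expansion
# ---------------------------------------------------------------------------

def expand_ambiguous_sequence(seq: str) -> list[str]:
    """Expand IUPAC ambiguity codes into every concrete A/C/G/T sequence.

    Sequences with more than three ambiguous positions are discarded (an
    empty list is returned); three fully degenerate positions therefore
    yield at most 4**3 = 64 expansions.  Expansion order is deterministic:
    alphabetical at each ambiguous position.
    """
    if not seq:
        raise ValueError("empty sequence")
    seq = seq.upper()
    choices: list[str] = []
    n_ambiguous = 0
    for pos, ch in enumerate(seq):
        try:
            opts = IUPAC_SETS[ch]
        except KeyError:
            raise ValueError(f"non-IUPAC character {ch!r} at position {pos}") from None
        if len(opts) > 1:
            n_ambiguous += 1
        choices.append(opts)
    if n_ambiguous > MAX_AMBIGUOUS_POSITIONS:
        return []
    return ["".join(p) for p in itertools.product(*choices)]


# ---------------------------------------------------------------------------
# reference set
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RefRecord:
    sequence_id: str
    sequence: str          # uppercase, unambiguous A/C/G/T
    taxonomy: str          # semicolon-delimited lineage ("" if unknown)
    source_id: str         # id of the un-expanded source record


@dataclass
class ReferenceSet:
    """Expanded, taxonomy-annotated full-length 16S reference sequences."""

    records: list[RefRecord]
    n_discarded_ambiguous: int = 0

    @property
    def J(self) -> int:
        return len(self.records)

    def __post_init__(self) -> None:
        if self.J < 1:
            raise ValueError("reference set must contain at least one record")
        ids = [r.sequence_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sequence ids in reference set")

    @classmethod
    def from_records(
        cls, raw: list[tuple[str, str, str]], expand: bool = True
    ) -> "ReferenceSet":
        """Build from (id, sequence, taxonomy) triples, expanding ambiguity.

        RNA-style U bases are converted to T.  Records with more than three
        ambiguous positions are dropped and counted.
        """
        records: list[RefRecord] = []
        dropped = 0
        for sid, seq, tax in raw:
            seq = seq.upper().replace("U", "T")
            variants = expand_ambiguous_sequence(seq) if expand else [seq]
            if not variants:
                dropped += 1
                continue
            if len(variants) == 1:
                records.append(RefRecord(sid, variants[0], tax, sid))
            else:
                for i, v in enumerate(variants, start=1):
                    records.append(RefRecord(f"{sid}.v{i}", v, tax, sid))
        return cls(records, n_discarded_ambiguous=dropped)

    @classmethod
    def from_fasta(
        cls, fasta: str | Path, taxonomy: str | Path | None = None
    ) -> "ReferenceSet":
        """Load a Greengenes/SILVA-style FASTA plus a 2-column taxonomy TSV.

        FASTA headers (first whitespace-delimited token) are the sequence
        ids; the taxonomy file maps id -> semicolon-ranked lineage.
        """
        tax_map: dict[str, str] = {}
        if taxonomy is not None:
            with open(taxonomy) as fh:
                for line in fh:
                    line = line.rstrip("\n")
                    if not line:
                        continue
                    sid, _, lineage = line.partition("\t")
                    tax_map[sid.strip()] = lineage.strip()
        raw = [
            (rec.id, str(rec.seq), tax_map.get(rec.id, ""))
            for rec in SeqIO.parse(str(fasta), "fasta")
        ]
        return cls.from_records(raw)

    def to_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for r in self.records:
                fh.write(f">{r.sequence_id}\n{r.sequence}\n")


# ---------------------------------------------------------------------------
# primers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PrimerPair:
    """A forward/reverse PCR primer pair defining one amplified region.

    Both primers are written 5'->3'; the reverse primer anneals to the
    forward strand as its reverse complement.
    """

    region_id: int
    forward: str
    reverse: str

    def __post_init__(self) -> None:
        for name, p in (("forward", self.forward), ("reverse", self.reverse)):
            if len(p) < 10:
                raise ValueError(f"{name} primer shorter than 10 nt")
            iupac_match_table(p)  # validates the alphabet


def load_primers(path: str | Path) -> list[PrimerPair]:
    """Read a tab-separated (region_id, forward, reverse) primer table."""
    pairs: list[PrimerPair] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            region, fwd, rev = line.split("\t")[:3]
            pairs.append(PrimerPair(int(region), fwd.upper(), rev.upper()))
    ids = [p.region_id for p in pairs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate region ids in primer table")
    if not pairs:
        raise ValueError(f"no primers found in {path}")
    return pairs


def default_primer_set() -> list[PrimerPair]:
    """The packaged six-pair primer set spanning ~80% of the 16S gene."""
    return load_primers(Path(__file__).parent / "data" / "primers_six.tsv")


def v4_primer_pair() -> PrimerPair:
    """Standard V4 primers (515F/806R-style degenerate pair)."""
    return load_primers(Path(__file__).parent / "data" / "primers_v4.tsv")[0]


# ---------------------------------------------------------------------------
# primer matching / amplicon location
# ---------------------------------------------------------------------------

def count_primer_mismatches(primer: str, window: str) -> int:
    """Mismatches between an IUPAC primer and an unambiguous window.

    A position matches iff the window base is a member of the primer base's
    IUPAC set; only substitutions are considered.
    """
    if len(primer) != len(window):
        raise ValueError(
            f"primer length {len(primer)} != window length {len(window)}"
        )
    table = iupac_match_table(primer)
    codes = encode(window)
    return int((~table[np.arange(len(primer)), codes]).sum())


@dataclass(frozen=True)
class AmpliconSite:
    """Best primer placement for one (taxon, region); 0-based half-open
    amplicon coordinates on the forward strand, primers excluded."""

    amplified: bool
    start: int = -1
    end: int = -1
    fwd_mismatches: int = -1
    rev_mismatches: int = -1

    @property
    def length(self) -> int:
        return max(self.end - self.start, 0) if self.amplified else 0


def _best_site(seq_codes: np.ndarray, table: np.ndarray, offset: int = 0
               ) -> tuple[int, int]:
    """Fewest-mismatch primer placement (leftmost on ties) at positions
    >= offset.  Returns (position, mismatches); (-1, big) if no window fits."""
    m = table.shape[0]
    n = seq_codes.shape[0]
    if n - offset < m:
        return -1, m + 1
    windows = np.lib.stride_tricks.sliding_window_view(seq_codes[offset:], m)
    ok = table[np.arange(m)[None, :], windows]
    mism = (~ok).sum(axis=1)
    pos = int(np.argmin(mism))
    return offset + pos, int(mism[pos])


def locate_amplicons(ref: ReferenceSet, primer: PrimerPair,
                     mismatch_cap: int = PRIMER_MISMATCH_CAP) -> list[AmpliconSite]:
    """In-silico PCR of one primer pair against every reference sequence.

    The forward strand is scanned for the best (fewest-mismatch, leftmost)
    forward-primer site; downstream of it, for the best site of the
    reverse-complemented reverse primer.  A taxon is amplified iff both best
    counts are <= the cap and the inter-primer amplicon is non-empty.
    """
    fwd_table = iupac_match_table(primer.forward)
    rev_rc = revcomp(primer.reverse)
    rev_table = iupac_match_table(rev_rc)
    sites: list[AmpliconSite] = []
    for rec in ref.records:
        codes = encode(rec.sequence)
        fpos, fmm = _best_site(codes, fwd_table)
        if fpos < 0:
            sites.append(AmpliconSite(False))
            continue
        amp_start = fpos + len(primer.forward)
        rpos, rmm = _best_site(codes, rev_table, offset=amp_start)
        amplified = fmm <= mismatch_cap and rmm <= mismatch_cap and rpos > amp_start
        sites.append(
            AmpliconSite(amplified, amp_start, rpos if rpos >= 0 else -1, fmm, rmm)
        )
    return sites


@dataclass
class AmpliconMap:
    """Per-region AmpliconSite lists, indexed [region_id][taxon j]."""

    sites: dict[int, list[AmpliconSite]]

    def site(self, region_id: int, j: int) -> AmpliconSite:
        return self.sites[region_id][j]


def build_amplicon_map(ref: ReferenceSet, primers: list[PrimerPair],
                       mismatch_cap: int = PRIMER_MISMATCH_CAP) -> AmpliconMap:
    return AmpliconMap(
        {p.region_id: locate_amplicons(ref, p, mismatch_cap) for p in primers}
    )


# ---------------------------------------------------------------------------
# region k-mer database
# ---------------------------------------------------------------------------

@dataclass
class RegionKmerDb:
    """Per-region k-mer database and sparse mixture matrix M (H x J).

    ``taxon_kmers[region][j]`` holds the k-mer(s) taxon j produces in that
    region: a 1-tuple for paired-end, a 2-tuple for single-end.  Regions
    whose amplicon is shorter than k are treated as not amplified for that
    taxon.  ``R[j]`` counts the amplified regions of taxon j; taxa with
    R=0 cannot be profiled with this primer set.
    """

    k: int
    mode: str                                 # "paired" | "single"
    region_ids: list[int]
    taxon_ids: list[str]
    taxonomies: list[str]
    taxon_kmers: dict[int, dict[int, tuple[str, ...]]]
    R: np.ndarray                             # (J,) int
    M: sp.csc_matrix                          # (H, J)
    row_keys: list[tuple[int, str]]           # row -> (region_id, kmer)
    row_index: dict[tuple[int, str], int]
    amplicons: AmpliconMap | None = None
    primers: list[PrimerPair] = field(default_factory=list)

    @property
    def J(self) -> int:
        return len(self.taxon_ids)

    @property
    def H(self) -> int:
        return len(self.row_keys)

    def region_rows(self, region_id: int) -> list[int]:
        return [i for i, (r, _) in enumerate(self.row_keys) if r == region_id]

    def read_length(self) -> int:
        """Length of a read string matched against this database."""
        return 2 * self.k if self.mode == "paired" else self.k

    def perfect_primer_regions(self, j: int) -> list[int]:
        """Regions where taxon j is amplified with zero primer mismatches."""
        if self.amplicons is None:
            return []
        out = []
        for r in self.region_ids:
            if j not in self.taxon_kmers[r]:
                continue
            s = self.amplicons.site(r, j)
            if s.fwd_mismatches == 0 and s.rev_mismatches == 0:
                out.append(r)
        return out

    def footprint(self, j: int, region_subset: list[int] | None = None
                  ) -> tuple[tuple[str, ...] | None, ...]:
        """Ordered tuple of taxon j's k-mers over the (subset of) regions;
        None marks a region where j is not amplified."""
        regions = sorted(region_subset) if region_subset else self.region_ids
        return tuple(
            tuple(sorted(self.taxon_kmers[r][j])) if j in self.taxon_kmers[r] else None
            for r in regions
        )

    def subset(self, region_subset: list[int]) -> "RegionKmerDb":
        """Restrict the database to a subset of regions (R and M rebuilt)."""
        missing = set(region_subset) - set(self.region_ids)
        if missing:
            raise ValueError(f"unknown region ids: {sorted(missing)}")
        kmers = {r: dict(self.taxon_kmers[r]) for r in sorted(region_subset)}
        db = _assemble(self.k, self.mode, sorted(region_subset), self.taxon_ids,
                       self.taxonomies, kmers)
        db.amplicons = self.amplicons
        db.primers = [p for p in self.primers if p.region_id in set(region_subset)]
        return db

    # -- persistence: a directory of a JSON manifest + gzipped TSV tables --

    def save(self, dbdir: str | Path) -> None:
        dbdir = Path(dbdir)
        dbdir.mkdir(parents=True, exist_ok=True)
        manifest = {
            "format_version": _DB_FORMAT_VERSION,
            "k": self.k,
            "mode": self.mode,
            "region_ids": self.region_ids,
            "J": self.J,
            "H": self.H,
            "primers": [
                [p.region_id, p.forward, p.reverse] for p in self.primers
            ],
        }
        (dbdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        with gzip.open(dbdir / "taxa.tsv.gz", "wt") as fh:
            for j, (tid, tax) in enumerate(zip(self.taxon_ids, self.taxonomies)):
                fh.write(f"{j}\t{tid}\t{int(self.R[j])}\t{tax}\n")
        with gzip.open(dbdir / "kmers.tsv.gz", "wt") as fh:
            for row, (region, kmer) in enumerate(self.row_keys):
                fh.write(f"{row}\t{region}\t{kmer}\n")
        coo = self.M.tocoo()
        with gzip.open(dbdir / "m.tsv.gz", "wt") as fh:
            for h, j, v in zip(coo.row, coo.col, coo.data):
                fh.write(f"{h}\t{j}\t{v:.10g}\n")
        if self.amplicons is not None:
            with gzip.open(dbdir / "amplicons.tsv.gz", "wt") as fh:
                for r, sites in sorted(self.amplicons.sites.items()):
                    for j, s in enumerate(sites):
                        fh.write(
                            f"{r}\t{j}\t{int(s.amplified)}\t{s.start}\t{s.end}"
                            f"\t{s.fwd_mismatches}\t{s.rev_mismatches}\n"
                        )

    @classmethod
    def load(cls, dbdir: str | Path) -> "RegionKmerDb":
        dbdir = Path(dbdir)
        manifest = json.loads((dbdir / "manifest.json").read_text())
        if manifest["format_version"] != _DB_FORMAT_VERSION:
            raise ValueError("unsupported database format version")
        taxon_ids: list[str] = []
        taxonomies: list[str] = []
        R: list[int] = []
        with gzip.open(dbdir / "taxa.tsv.gz", "rt") as fh:
            for line in fh:
                _, tid, r, tax = line.rstrip("\n").split("\t", 3)
                taxon_ids.append(tid)
                taxonomies.append(tax)
                R.append(int(r))
        row_keys: list[tuple[int, str]] = []
        with gzip.open(dbdir / "kmers.tsv.gz", "rt") as fh:
            for line in fh:
                _, region, kmer = line.rstrip("\n").split("\t")
                row_keys.append((int(region), kmer))
        rows, cols, vals = [], [], []
        with gzip.open(dbdir / "m.tsv.gz", "rt") as fh:
            for line in fh:
                h, j, v = line.rstrip("\n").split("\t")
                rows.append(int(h))
                cols.append(int(j))
                vals.append(float(v))
        M = sp.csc_matrix(
            (vals, (rows, cols)), shape=(len(row_keys), len(taxon_ids))
        )
        taxon_kmers: dict[int, dict[int, tuple[str, ...]]] = {
            r: {} for r in manifest["region_ids"]
        }
        coo = M.tocoo()
        per_taxon: dict[tuple[int, int], list[str]] = {}
        for h, j in zip(coo.row, coo.col):
            region, kmer = row_keys[h]
            per_taxon.setdefault((region, int(j)), []).append(kmer)
        for (region, j), kms in per_taxon.items():
            taxon_kmers[region][j] = tuple(sorted(kms))
        amplicons = None
        amp_path = dbdir / "amplicons.tsv.gz"
        if amp_path.exists():
            sites: dict[int, list[tuple[int, AmpliconSite]]] = {}
            with gzip.open(amp_path, "rt") as fh:
                for line in fh:
                    r, j, amp, start, end, fmm, rmm = line.rstrip("\n").split("\t")
                    sites.setdefault(int(r), []).append(
                        (int(j), AmpliconSite(bool(int(amp)), int(start),
                                              int(end), int(fmm), int(rmm)))
                    )
            amplicons = AmpliconMap(
                {r: [s for _, s in sorted(v)] for r, v in sites.items()}
            )
        primers = [PrimerPair(int(r), f, v) for r, f, v in manifest["primers"]]
        return cls(
            k=manifest["k"], mode=manifest["mode"],
            region_ids=list(manifest["region_ids"]), taxon_ids=taxon_ids,
            taxonomies=taxonomies, taxon_kmers=taxon_kmers,
            R=np.asarray(R, dtype=int), M=M, row_keys=row_keys,
            row_index={key: i for i, key in enumerate(row_keys)},
            amplicons=amplicons, primers=primers,
        )


def _assemble(k: int, mode: str, region_ids: list[int], taxon_ids: list[str],
              taxonomies: list[str],
              taxon_kmers: dict[int, dict[int, tuple[str, ...]]]) -> RegionKmerDb:
    """Build R, the row index, and sparse M from per-taxon region k-mers."""
    J = len(taxon_ids)
    R = np.zeros(J, dtype=int)
    for r in region_ids:
        for j in taxon_kmers[r]:
            R[j] += 1
    row_index: dict[tuple[int, str], int] = {}
    row_keys: list[tuple[int, str]] = []
    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []
    weight = 1.0 if mode == "paired" else 0.5
    for r in region_ids:
        for j, kmers in sorted(taxon_kmers[r].items()):
            for kmer in kmers:
                key = (r, kmer)
                h = row_index.get(key)
                if h is None:
                    h = len(row_keys)
                    row_index[key] = h
                    row_keys.append(key)
                rows.append(h)
                cols.append(j)
                vals.append(weight / R[j])
    M = sp.csc_matrix((vals, (rows, cols)), shape=(len(row_keys), J))
    M.sum_duplicates()
    return RegionKmerDb(
        k=k, mode=mode, region_ids=list(region_ids), taxon_ids=list(taxon_ids),
        taxonomies=list(taxonomies), taxon_kmers=taxon_kmers, R=R, M=M,
        row_keys=row_keys, row_index=row_index,
    )


def build_region_kmer_db(
    ref: ReferenceSet,
    primers: list[PrimerPair],
    k: int,
    mode: str = "paired",
    mismatch_cap: int = PRIMER_MISMATCH_CAP,
    amplicons: AmpliconMap | None = None,
) -> RegionKmerDb:
    """Locate amplicons for every primer pair and assemble the k-mer DB.

    Paired-end mode emits one concatenated forward||reverse k-mer per
    (taxon, region); single-end mode emits the two k-length ends as separate
    rows.  Amplicons shorter than k are treated as not amplified.
    """
    if not primers:
        raise ValueError("empty primer set")
    if k < 1:
        raise ValueError("k must be >= 1")
    if mode not in ("paired", "single"):
        raise ValueError(f"unknown mode {mode!r}")
    if amplicons is None:
        amplicons = build_amplicon_map(ref, primers, mismatch_cap)
    region_ids = sorted(p.region_id for p in primers)
    taxon_kmers: dict[int, dict[int, tuple[str, ...]]] = {r: {} for r in region_ids}
    for r in region_ids:
        sites = amplicons.sites[r]
        for j, rec in enumerate(ref.records):
            s = sites[j]
            if not s.amplified or s.length < k:
                continue
            amp = rec.sequence[s.start:s.end]
            head = amp[:k]
            tail = revcomp(amp)[:k]
            if mode == "paired":
                taxon_kmers[r][j] = (head + tail,)
            else:
                taxon_kmers[r][j] = (head, tail)
    db = _assemble(
        k, mode, region_ids,
        [rec.sequence_id for rec in ref.records],
        [rec.taxonomy for rec in ref.records],
        taxon_kmers,
    )
    db.amplicons = amplicons
    db.primers = sorted(primers, key=lambda p: p.region_id)
    return db


# ---------------------------------------------------------------------------
# theoretical resolution (footprint groups)
# ---------------------------------------------------------------------------

@dataclass
class FootprintIndex:
    """Partition of amplifiable taxa into identical-footprint groups."""

    groups: dict[tuple, list[int]]      # footprint -> sorted taxon indices
    region_subset: list[int]

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    @property
    def n_taxa(self) -> int:
        return sum(len(v) for v in self.groups.values())

    def group_sizes(self) -> np.ndarray:
        return np.asarray(sorted(len(v) for v in self.groups.values()))

    def size_histogram(self) -> dict[int, int]:
        hist: dict[int, int] = {}
        for members in self.groups.values():
            hist[len(members)] = hist.get(len(members), 0) + 1
        return dict(sorted(hist.items()))

    def unique_fraction(self) -> float:
        if self.n_taxa == 0:
            return float("nan")
        singletons = sum(len(v) for v in self.groups.values() if len(v) == 1)
        return singletons / self.n_taxa

    def group_size_of(self) -> dict[int, int]:
        """taxon index -> size of its group."""
        out: dict[int, int] = {}
        for members in self.groups.values():
            for j in members:
                out[j] = len(members)
        return out


def compute_theoretical_groups(
    db: RegionKmerDb, region_subset: list[int] | None = None
) -> FootprintIndex:
    """Group taxa by identical footprint over the given regions.

    Taxa amplified in none of the regions are excluded; every other taxon
    falls in exactly one group.  Two taxa sharing all their k-mers over the
    subset (including the pattern of non-amplified regions) are
    indistinguishable by profiling restricted to that subset.
    """
    regions = sorted(region_subset) if region_subset else list(db.region_ids)
    if not regions:
        raise ValueError("empty region subset")
    if not set(regions) <= set(db.region_ids):
        raise ValueError("region subset not contained in database regions")
    groups: dict[tuple, list[int]] = {}
    for j in range(db.J):
        fp = db.footprint(j, regions)
        if all(entry is None for entry in fp):
            continue
        groups.setdefault(fp, []).append(j)
    return FootprintIndex(groups=groups, region_subset=regions)
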
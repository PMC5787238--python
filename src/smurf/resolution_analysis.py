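"""Footprint groups, ambiguity (effective sequence counts), and profile
post-processing.

Reconstructed full-length sequences that share the same k-mers over every
amplified region (the same "footprint") cannot be told apart by the
profiler; such an equivalence class is a *group*.  Resolution is quantified
per profiled bacterium as the *ambiguity* — the effective number of
reference sequences assigned to it, computed as the exponent of the Shannon
entropy of the per-sequence weight vector.  For a single group with equal
weights this is exactly the group size; lower ambiguity means higher
resolution.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .profiling_core import ProfileResult
from .reference_db import RegionKmerDb

DEFAULT_MIN_GROUP_FREQUENCY = 0.001

_RANK_PREFIX = {
    "domain": "k__", "kingdom": "k__", "phylum": "p__", "class": "c__",
    "order": "o__", "family": "f__", "genus": "g__", "species": "s__",
}


def taxonomy_label(lineage: str, level: str = "species") -> str:
    """Extract one rank from a semicolon-delimited lineage string.

    Understands Greengenes-style prefixes (``s__``); falls back to the last
    non-empty field (or the whole string) when no prefixed rank is present.
    """
    fields = [f.strip() for f in lineage.split(";") if f.strip()]
    prefix = _RANK_PREFIX.get(level.lower())
    if prefix is not None:
        for f in fields:
            if f.startswith(prefix) and len(f) > len(prefix):
                return f
    return fields[-1] if fields else lineage


@dataclass
class Group:
    """An identical-footprint equivalence class of supported sequences."""

    footprint: tuple
    member_ids: list[str]
    member_x: np.ndarray
    taxonomy: str

    @property
    def frequency(self) -> float:
        return float(self.member_x.sum())

    @property
    def size(self) -> int:
        return len(self.member_ids)


def assign_groups(result: ProfileResult, db: RegionKmerDb) -> list[Group]:
    """Partition supported taxa (x > 0) into footprint groups.

    Group frequency is the summed x of its members; the representative
    taxonomy is the highest-frequency member's.  Output is ordered by
    descending frequency, then lexicographic footprint.
    """
    by_fp: dict[tuple, list[int]] = {}
    for i in result.supported():
        j = int(result.taxon_indices[i])
        by_fp.setdefault(db.footprint(j), []).append(i)
    groups = []
    for fp, members in by_fp.items():
        xs = np.asarray([result.x[i] for i in members])
        rep = members[int(np.argmax(xs))]
        groups.append(
            Group(
                footprint=fp,
                member_ids=[result.taxon_ids[i] for i in members],
                member_x=xs,
                taxonomy=result.taxonomies[rep],
            )
        )
    groups.sort(key=lambda g: (-g.frequency, repr(g.footprint)))
    return groups


def compute_ambiguity(groups: list[Group]) -> float:
    """Effective number of sequences over a set of matched groups.

    Each group's frequency is split equally among its member sequences; the
    resulting weight vector is normalized and its Shannon-entropy exponent
    (natural log) returned.  A single group of size G with any positive
    frequency gives exactly G.
    """
    if not groups:
        raise ValueError("no groups matched")
    weights: list[float] = []
    for g in groups:
        share = g.frequency / g.size
        weights.extend([share] * g.size)
    w = np.asarray(weights, dtype=float)
    total = w.sum()
    if total <= 0:
        raise ValueError("matched groups carry zero total frequency")
    w = w / total
    w = w[w > 0]
    return float(np.exp(-(w * np.log(w)).sum()))


@dataclass
class AmbiguityReport:
    """Per-label ambiguity scores plus the cohort mean."""

    per_label: dict[str, tuple[float, int, int]]  # label -> (ambiguity, n_groups, n_sequences)

    @property
    def mean_ambiguity(self) -> float:
        vals = [v[0] for v in self.per_label.values()]
        return float(np.mean(vals)) if vals else float("nan")

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("label\tambiguity\tn_groups\tn_sequences\n")
            for label, (amb, ng, ns) in sorted(self.per_label.items()):
                fh.write(f"{label}\t{amb:.6g}\t{ng}\t{ns}\n")


def ambiguity_by_label(
    groups: list[Group], level: str = "species"
) -> AmbiguityReport:
    """Group-to-bacterium matching by taxonomy label, then ambiguity.

    All groups whose representative taxonomy maps to the same label are
    considered assigned to that bacterium (a bacterium may correspond to
    several groups, e.g. through distinct operons or profiling errors).
    """
    by_label: dict[str, list[Group]] = {}
    for g in groups:
        by_label.setdefault(taxonomy_label(g.taxonomy, level), []).append(g)
    per_label = {
        label: (
            compute_ambiguity(gs),
            len(gs),
            sum(g.size for g in gs),
        )
        for label, gs in by_label.items()
    }
    return AmbiguityReport(per_label=per_label)


@dataclass
class MergedEntry:
    label: str
    frequency: float
    n_groups: int
    member_ids: list[str]


def postprocess_profile(
    groups: list[Group],
    min_frequency: float = DEFAULT_MIN_GROUP_FREQUENCY,
    level: str = "species",
) -> list[MergedEntry]:
    """Merge groups by taxonomy label, filter, and renormalize.

    Groups sharing the same (default species-level) label have their
    frequencies added; merged entries below ``min_frequency`` are discarded
    and the remainder renormalized to sum to one.
    """
    merged: dict[str, MergedEntry] = {}
    for g in groups:
        label = taxonomy_label(g.taxonomy, level)
        entry = merged.get(label)
        if entry is None:
            merged[label] = MergedEntry(label, g.frequency, 1, list(g.member_ids))
        else:
            entry.frequency += g.frequency
            entry.n_groups += 1
            entry.member_ids.extend(g.member_ids)
    kept = [e for e in merged.values() if e.frequency >= min_frequency]
    if not kept:
        raise ValueError(
            "every merged entry fell below min_frequency "
            f"({min_frequency}); lower the threshold"
        )
    total = sum(e.frequency for e in kept)
    for e in kept:
        e.frequency /= total
    kept.sort(key=lambda e: (-e.frequency, e.label))
    return kept


def write_groups_tsv(groups: list[Group], path: str | Path) -> None:
    import hashlib

    with open(path, "w") as fh:
        fh.write("group_id\tfrequency\tsize\tfootprint_hash\tmember_ids\ttaxonomy\n")
        for gid, g in enumerate(groups):
            digest = hashlib.sha1(repr(g.footprint).encode()).hexdigest()[:12]
            fh.write(
                f"{gid}\t{g.frequency:.10g}\t{g.size}\t"
                f"{digest}\t{','.join(g.member_ids)}\t"
                f"{g.taxonomy}\n"
            )
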
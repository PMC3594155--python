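"""Classification and filtering of mapped Hi-C read pairs into contacts.

A Hi-C read pair evidences one spatial contact between the two genomic
locations its ends map to.  Aligners may report several candidate locations
per end; this module resolves that ambiguity with one of two strategies:

``strict_unique``
    Keep a pair only when both ends map to exactly one location (the default,
    most stringent strategy; the noise-reduction choice for quantitative
    results).

``four_case``
    Additionally rescue pairs with up to two candidate locations per end,
    using the expected DNA insert length (~2 kb) and the read length to decide
    which candidate pair is plausible.  Ends with three or more candidate
    locations are always discarded.

Intra-chromosomal pairs closer than ``min_separation`` (default 2 kb, the
insert length) are removed: they are dominated by self-ligation and unligated
insert artifacts rather than genuine long-range contacts.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Iterator, NamedTuple, Sequence, Union

import pandas as pd

from .genome import Genome


class CandidateLocation(NamedTuple):
    """One candidate mapped location of a read end (1-based read start)."""

    chromosome: str
    position: int
    strand: str = "+"


@dataclass(frozen=True)
class ReadPairRecord:
    """A paired-end read with candidate mapped locations for each end."""

    read_id: str
    end1: tuple[CandidateLocation, ...]
    end2: tuple[CandidateLocation, ...]
    read_length: int = 100

    def __post_init__(self):
        if self.read_length <= 0:
            raise ValueError("read_length must be positive")


class Contact(NamedTuple):
    """An accepted spatial contact, in canonical (chromosome, position) order."""

    chrom_a: str
    pos_a: int
    chrom_b: str
    pos_b: int


@dataclass(frozen=True)
class Rejection:
    reason: str


STRATEGIES = ("strict_unique", "four_case")

#: rejection reasons reported by :func:`filter_pair_stream`
REASONS = ("unmapped", "multi_mapped", "ambiguous", "short_separation", "duplicate")


@dataclass(frozen=True)
class FilterPolicy:
    """Pair-acceptance policy.

    Parameters
    ----------
    strategy:
        ``strict_unique`` or ``four_case`` (see module docstring).
    min_separation:
        Minimum same-chromosome separation (bp) for an accepted contact.
    insert_length:
        Expected DNA insert length (bp), used by the four-case strategy to
        recognise which ambiguous candidate is the physically linked mate.
    dedup:
        Collapse identical contacts (off by default: duplicates are kept).
    """

    strategy: str = "strict_unique"
    min_separation: int = 2000
    insert_length: int = 2000
    dedup: bool = False

    def __post_init__(self):
        if self.strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if self.min_separation < 0:
            raise ValueError("min_separation must be >= 0")
        if self.insert_length <= 0:
            raise ValueError("insert_length must be positive")


def canonical_contact(loc_a: CandidateLocation, loc_b: CandidateLocation,
                      genome: Genome) -> Contact:
    """Orient two mapped ends into canonical (chromosome order, position) order."""
    ka = (genome.index(loc_a.chromosome), loc_a.position)
    kb = (genome.index(loc_b.chromosome), loc_b.position)
    if kb < ka:
        loc_a, loc_b = loc_b, loc_a
    return Contact(loc_a.chromosome, loc_a.position, loc_b.chromosome, loc_b.position)


def _validate(record: ReadPairRecord, genome: Genome) -> None:
    for loc in (*record.end1, *record.end2):
        if loc.chromosome not in genome:
            raise ValueError(
                f"read {record.read_id}: unknown chromosome {loc.chromosome!r}")
        if not 1 <= loc.position <= genome.length(loc.chromosome):
            raise ValueError(
                f"read {record.read_id}: position {loc.position} outside "
                f"{loc.chromosome}")


def _resolve_ambiguous(unique: CandidateLocation,
                       cands: Sequence[CandidateLocation],
                       policy: FilterPolicy):
    """Cases two/three: one unique end, one end with two candidates.

    The pair is valid when one candidate lies within the insert length of the
    unique end; that nearby candidate is taken to be the physically linked
    insert end, and the *other* candidate is recorded as the contact partner.
    """
    near = [c for c in cands
            if c.chromosome == unique.chromosome
            and abs(c.position - unique.position) <= policy.insert_length]
    if not near:
        return Rejection("ambiguous")
    linked = min(near, key=lambda c: abs(c.position - unique.position))
    partner = cands[1] if cands[0] == linked else cands[0]
    return unique, partner


def _resolve_double(end1: Sequence[CandidateLocation],
                    end2: Sequence[CandidateLocation],
                    read_length: int):
    """Case four: two candidates on each end (A,B vs C,D).

    Valid when |A-C| < read length and |B-D| < read length, i.e. the two
    candidate sets pair up into two near-identical mapped pairs; the first
    candidate of each end is then emitted.
    """
    a, b = end1
    c, d = end2
    ok = (a.chromosome == c.chromosome and abs(a.position - c.position) < read_length
          and b.chromosome == d.chromosome and abs(b.position - d.position) < read_length)
    if not ok:
        return Rejection("ambiguous")
    return a, c


def classify_pair(record: ReadPairRecord, policy: FilterPolicy,
                  genome: Genome) -> Union[Contact, Rejection]:
    """Classify one read pair into a contact or a rejection.

    The separation filter is *not* applied here; see
    :func:`apply_separation_filter` and :func:`filter_pair_stream`.
    """
    _validate(record, genome)
    n1, n2 = len(record.end1), len(record.end2)
    if n1 == 0 or n2 == 0:
        return Rejection("unmapped")
    if policy.strategy == "strict_unique":
        if n1 == 1 and n2 == 1:
            return canonical_contact(record.end1[0], record.end2[0], genome)
        return Rejection("multi_mapped")
    # four_case
    if n1 >= 3 or n2 >= 3:
        return Rejection("multi_mapped")
    if n1 == 1 and n2 == 1:
        resolved = (record.end1[0], record.end2[0])
    elif n1 == 1:
        resolved = _resolve_ambiguous(record.end1[0], record.end2, policy)
    elif n2 == 1:
        resolved = _resolve_ambiguous(record.end2[0], record.end1, policy)
    else:
        resolved = _resolve_double(record.end1, record.end2, record.read_length)
    if isinstance(resolved, Rejection):
        return resolved
    return canonical_contact(resolved[0], resolved[1], genome)


def apply_separation_filter(contact: Contact, policy: FilterPolicy) -> bool:
    """True iff the contact is inter-chromosomal or separated by >= min_separation."""
    if contact.chrom_a != contact.chrom_b:
        return True
    return abs(contact.pos_a - contact.pos_b) >= policy.min_separation


def filter_pair_stream(records: Iterable[ReadPairRecord], policy: FilterPolicy,
                       genome: Genome) -> tuple[list[Contact], dict[str, int]]:
    """Classify and filter a stream of read pairs.

    Returns the accepted contacts and a per-reason tally.  Every input record
    is counted exactly once: ``stats['accepted'] + sum(rejections) == n``.
    """
    stats: Counter[str] = Counter({"accepted": 0})
    contacts: list[Contact] = []
    seen: set[Contact] = set()
    for record in records:
        outcome = classify_pair(record, policy, genome)
        if isinstance(outcome, Rejection):
            stats[outcome.reason] += 1
            continue
        if not apply_separation_filter(outcome, policy):
            stats["short_separation"] += 1
            continue
        if policy.dedup:
            if outcome in seen:
                stats["duplicate"] += 1
                continue
            seen.add(outcome)
        stats["accepted"] += 1
        contacts.append(outcome)
    return contacts, dict(stats)


# ---------------------------------------------------------------------------
# plain-text I/O

def read_pair_table(path) -> Iterator[ReadPairRecord]:
    """Parse a mapped read-pair table.

    Two dialects are accepted, both tab-separated, one line per read pair:

    * full: ``read_id  n1  (chrom pos strand) x n1  n2  (chrom pos strand) x n2
      read_length``
    * simplified 5-column for already-unique data:
      ``read_id  chrom1  pos1  chrom2  pos2`` (read length defaults to 100).
    """
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            tok = line.split("\t")
            try:
                if len(tok) == 5:
                    yield ReadPairRecord(
                        read_id=tok[0],
                        end1=(CandidateLocation(tok[1], int(tok[2])),),
                        end2=(CandidateLocation(tok[3], int(tok[4])),),
                    )
                else:
                    yield _parse_full(tok)
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}: malformed line {lineno}: {exc}") from exc


def _parse_full(tok: list[str]) -> ReadPairRecord:
    read_id = tok[0]
    n1 = int(tok[1])
    pos = 2
    end1 = tuple(CandidateLocation(tok[pos + 3 * i], int(tok[pos + 3 * i + 1]),
                                   tok[pos + 3 * i + 2]) for i in range(n1))
    pos += 3 * n1
    n2 = int(tok[pos])
    pos += 1
    end2 = tuple(CandidateLocation(tok[pos + 3 * i], int(tok[pos + 3 * i + 1]),
                                   tok[pos + 3 * i + 2]) for i in range(n2))
    pos += 3 * n2
    if pos != len(tok) - 1:
        raise ValueError(f"expected {pos + 1} fields, got {len(tok)}")
    return ReadPairRecord(read_id, end1, end2, read_length=int(tok[pos]))


def write_pair_table(records: Iterable[ReadPairRecord], path) -> None:
    """Write records in the full dialect (round-trips through the reader)."""
    with open(path, "w") as fh:
        for r in records:
            fields = [r.read_id, str(len(r.end1))]
            for loc in r.end1:
                fields += [loc.chromosome, str(loc.position), loc.strand]
            fields.append(str(len(r.end2)))
            for loc in r.end2:
                fields += [loc.chromosome, str(loc.position), loc.strand]
            fields.append(str(r.read_length))
            fh.write("\t".join(fields) + "\n")


def write_contacts(contacts: Iterable[Contact], path) -> None:
    with open(path, "w") as fh:
        for c in contacts:
            fh.write(f"{c.chrom_a}\t{c.pos_a}\t{c.chrom_b}\t{c.pos_b}\n")


def read_contacts(path) -> list[Contact]:
    df = read_contacts_frame(path)
    return [Contact(*row) for row in df.itertuples(index=False)]


def read_contacts_frame(path) -> pd.DataFrame:
    """Contacts file as a DataFrame (chrom_a, pos_a, chrom_b, pos_b)."""
    return pd.read_csv(path, sep="\t", header=None,
                       names=["chrom_a", "pos_a", "chrom_b", "pos_b"],
                       dtype={"chrom_a": str, "chrom_b": str})


def contacts_frame(contacts) -> pd.DataFrame:
    """Normalise a contact list (or frame) to a DataFrame."""
    if isinstance(contacts, pd.DataFrame):
        return contacts
    return pd.DataFrame(contacts, columns=["chrom_a", "pos_a", "chrom_b", "pos_b"])
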
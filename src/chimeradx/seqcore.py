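"""Sequence primitives: alignment, identity, translation, ORFs, databases.

Conventions used throughout the package:

* residue alphabet is the 20 standard amino acids plus ``X`` (unknown) and
  ``-`` (gap); sequences are plain upper-case strings;
* residue coordinates in reports are 1-based inclusive;
* pairwise and progressive alignment use BLOSUM62 with affine gap costs
  (open 11, extend 1) unless told otherwise;
* DP tie-breaking prefers match over consuming the first sequence over
  consuming the second, so all alignments are bit-stable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Align import substitution_matrices
from Bio.Seq import Seq
from scipy.cluster.hierarchy import linkage

from ._kernels import gotoh_global
from .substitution import AMINO_ACIDS

ALPHABET = AMINO_ACIDS + "X"  # index 20 = X
CHAR_INDEX = {c: i for i, c in enumerate(ALPHABET)}
GAP = "-"
DOMAINS_OF_LIFE = ("Eukaryota", "Bacteria", "Archaea", "Virus", "Unknown")

DEFAULT_GAP_OPEN = 11.0
DEFAULT_GAP_EXTEND = 1.0


def blosum62() -> np.ndarray:
    """BLOSUM62 as a 21x21 array over ``ALPHABET`` (X column included)."""
    mat = substitution_matrices.load("BLOSUM62")
    out = np.zeros((21, 21))
    for i, a in enumerate(ALPHABET):
        for j, b in enumerate(ALPHABET):
            out[i, j] = mat[a][b]
    return out


_BLOSUM62 = None


def default_substitution_table() -> np.ndarray:
    global _BLOSUM62
    if _BLOSUM62 is None:
        _BLOSUM62 = blosum62()
    return _BLOSUM62


def encode_residues(seq: str) -> np.ndarray:
    """Index-encode a residue string; raises on illegal characters."""
    try:
        return np.array([CHAR_INDEX[c] for c in seq], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"illegal residue {exc.args[0]!r}") from None


@dataclass
class TaxLabeledSequence:
    """A protein sequence with taxonomy labels, the atom of every database."""

    id: str
    residues: str
    domain_of_life: str = "Unknown"
    category: str = "background"
    source_ids: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} is empty")
        if self.domain_of_life not in DOMAINS_OF_LIFE:
            raise ValueError(f"unknown domain of life {self.domain_of_life!r}")
        if not self.source_ids:
            self.source_ids = frozenset({self.id})


class SequenceDatabase:
    """An id-indexed collection of :class:`TaxLabeledSequence` records."""

    def __init__(self, records: Iterable[TaxLabeledSequence]):
        self.records = list(records)
        self._index = {}
        for rec in self.records:
            if rec.id in self._index:
                raise ValueError(f"duplicate sequence id {rec.id!r}")
            self._index[rec.id] = rec

    def __len__(self):
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __contains__(self, seq_id):
        return seq_id in self._index

    def __getitem__(self, seq_id) -> TaxLabeledSequence:
        return self._index[seq_id]

    @property
    def ids(self):
        return [rec.id for rec in self.records]

    def taxonomy(self) -> dict:
        return {rec.id: (rec.domain_of_life, rec.category) for rec in self.records}


@dataclass
class Alignment:
    """A multiple sequence alignment stored as ordered (id, gapped row) pairs."""

    rows: list  # list[(id, gapped sequence)]

    def __post_init__(self):
        if not self.rows:
            raise ValueError("alignment has no rows")
        lengths = {len(row) for _, row in self.rows}
        if len(lengths) != 1:
            raise ValueError("alignment rows differ in length")
        ids = [rid for rid, _ in self.rows]
        if len(set(ids)) != len(ids):
            raise ValueError("alignment row ids are not unique")
        legal = set(ALPHABET) | {GAP}
        for rid, row in self.rows:
            bad = set(row) - legal
            if bad:
                raise ValueError(f"illegal characters {bad} in row {rid!r}")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0][1])

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def ids(self):
        return [rid for rid, _ in self.rows]

    def ungapped(self, rid: str) -> str:
        row = dict(self.rows)[rid]
        return row.replace(GAP, "")

    def column(self, j: int) -> str:
        """Column ``j`` (0-based) as a string."""
        return "".join(row[j] for _, row in self.rows)

    def occupancy(self) -> np.ndarray:
        arr = np.array([list(row) for _, row in self.rows])
        return (arr != GAP).mean(axis=0)

    def select_columns(self, keep) -> "Alignment":
        keep = list(keep)
        return Alignment([(rid, "".join(row[j] for j in keep)) for rid, row in self.rows])


# ---------------------------------------------------------------------------
# pairwise alignment


def _traceback_global(a: str, b: str, state: int, ptr: np.ndarray):
    i, j = len(a), len(b)
    out_a, out_b = [], []
    while i > 0 or j > 0:
        p = ptr[state, i, j]
        if state == 0:
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            i -= 1
            j -= 1
        elif state == 1:
            out_a.append(a[i - 1])
            out_b.append(GAP)
            i -= 1
        else:
            out_a.append(GAP)
            out_b.append(b[j - 1])
            j -= 1
        state = p
        if i == 0 and j > 0:
            state = 2
        elif j == 0 and i > 0:
            state = 1
    return "".join(reversed(out_a)), "".join(reversed(out_b))


def global_align(a: str, b: str, substitution_table: np.ndarray | None = None,
                 gap_open: float = DEFAULT_GAP_OPEN,
                 gap_extend: float = DEFAULT_GAP_EXTEND):
    """Optimal affine-gap global alignment.

    Returns ``((aligned_a, aligned_b), score)``.  A gap of length k costs
    ``gap_open + k * gap_extend``.
    """
    if not a or not b:
        raise ValueError("cannot align empty sequences")
    sub = default_substitution_table() if substitution_table is None else substitution_table
    ea, eb = encode_residues(a), encode_residues(b)
    score, state, ptr = gotoh_global(ea, eb, sub, float(gap_open), float(gap_extend))
    aligned = _traceback_global(a, b, state, ptr)
    return aligned, float(score)


def percent_identity(aligned_pair) -> float:
    """Identical fraction over columns where both rows are non-gap."""
    ra, rb = aligned_pair
    if len(ra) != len(rb):
        raise ValueError("aligned rows differ in length")
    both = matches = 0
    for x, y in zip(ra, rb):
        if x != GAP and y != GAP:
            both += 1
            if x == y:
                matches += 1
    return matches / both if both else 0.0


# ---------------------------------------------------------------------------
# progressive multiple alignment


def _kmer_distance(seqs: Sequence[str], k: int = 3) -> np.ndarray:
    """Fractional-common-k-mer distance matrix (the classic draft-MSA
    guide-tree measure)."""
    sets = []
    for s in seqs:
        if len(s) >= k:
            sets.append({s[i:i + k] for i in range(len(s) - k + 1)})
        else:
            sets.append({s})
    n = len(seqs)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            denom = min(len(sets[i]), len(sets[j]))
            frac = len(sets[i] & sets[j]) / denom if denom else 0.0
            dist[i, j] = dist[j, i] = 1.0 - frac
    return dist


def _profile_columns(rows: list[str], sub: np.ndarray) -> np.ndarray:
    """Per-column expected-score profile: counts over the 21-letter alphabet."""
    n_cols = len(rows[0])
    counts = np.zeros((n_cols, 21))
    for row in rows:
        for j, c in enumerate(row):
            if c != GAP:
                counts[j, CHAR_INDEX[c]] += 1
    return counts


def _merge_alignments(rows_a: list[str], rows_b: list[str], sub: np.ndarray,
                      gap_open: float, gap_extend: float):
    ca = _profile_columns(rows_a, sub)
    cb = _profile_columns(rows_b, sub)
    wa = ca.sum(axis=1, keepdims=True).clip(min=1)
    wb = cb.sum(axis=1, keepdims=True).clip(min=1)
    colscore = (ca / wa) @ sub @ (cb / wb).T
    ia = np.arange(ca.shape[0], dtype=np.int64)
    ib = np.arange(cb.shape[0], dtype=np.int64)
    _, state, ptr = gotoh_global(ia, ib, colscore, gap_open, gap_extend)
    # traceback over column indices
    i, j = len(ia), len(ib)
    ops = []
    while i > 0 or j > 0:
        p = ptr[state, i, j]
        if state == 0:
            ops.append("M")
            i -= 1
            j -= 1
        elif state == 1:
            ops.append("A")
            i -= 1
        else:
            ops.append("B")
            j -= 1
        state = p
        if i == 0 and j > 0:
            state = 2
        elif j == 0 and i > 0:
            state = 1
    ops.reverse()
    out_a = [[] for _ in rows_a]
    out_b = [[] for _ in rows_b]
    i = j = 0
    for op in ops:
        if op in ("M", "A"):
            for r, row in enumerate(rows_a):
                out_a[r].append(row[i])
            i += 1
        else:
            for r in range(len(rows_a)):
                out_a[r].append(GAP)
        if op in ("M", "B"):
            for r, row in enumerate(rows_b):
                out_b[r].append(row[j])
            j += 1
        else:
            for r in range(len(rows_b)):
                out_b[r].append(GAP)
    return ["".join(r) for r in out_a], ["".join(r) for r in out_b]


def progressive_msa(seqs: Sequence[str], ids: Sequence[str] | None = None,
                    substitution_table: np.ndarray | None = None,
                    gap_open: float = DEFAULT_GAP_OPEN,
                    gap_extend: float = DEFAULT_GAP_EXTEND) -> Alignment:
    """Progressive multiple alignment over a UPGMA k-mer guide tree.

    Sequences are merged profile-to-profile up the guide tree; removing the
    gaps of any output row reproduces the corresponding input exactly.
    """
    seqs = list(seqs)
    if len(seqs) < 2:
        raise ValueError("progressive_msa needs at least 2 sequences")
    if ids is None:
        ids = [f"seq{i + 1}" for i in range(len(seqs))]
    ids = list(ids)
    sub = default_substitution_table() if substitution_table is None else substitution_table
    for s in seqs:
        encode_residues(s)  # validates
    dist = _kmer_distance(seqs)
    n = len(seqs)
    if n == 2:
        merged = _merge_alignments([seqs[0]], [seqs[1]], sub, gap_open, gap_extend)
        return Alignment(list(zip(ids, merged[0] + merged[1])))
    condensed = dist[np.triu_indices(n, k=1)]
    tree = linkage(condensed, method="average")
    clusters: dict[int, tuple[list[int], list[str]]] = {
        i: ([i], [seqs[i]]) for i in range(n)
    }
    for step, (left, right, _, _) in enumerate(tree):
        la, ra = clusters.pop(int(left)), clusters.pop(int(right))
        rows_a, rows_b = _merge_alignments(la[1], ra[1], sub, gap_open, gap_extend)
        clusters[n + step] = (la[0] + ra[0], rows_a + rows_b)
    order, rows = clusters.popitem()[1]
    # restore input order
    paired = sorted(zip(order, rows))
    return Alignment([(ids[i], row) for i, row in paired])


# ---------------------------------------------------------------------------
# trimming and profiles


def trim_by_occupancy(alignment: Alignment, min_occupancy: float = 0.70) -> Alignment:
    """Keep exactly the columns whose non-gap fraction is >= the threshold."""
    if not (0.0 < min_occupancy <= 1.0):
        raise ValueError("min_occupancy must lie in (0, 1]")
    occ = alignment.occupancy()
    keep = [j for j in range(alignment.n_columns) if occ[j] >= min_occupancy - 1e-12]
    return alignment.select_columns(keep)


def align_to_profile(profile, seq: str):
    """Align a sequence to a profile model (delegates to profile_search)."""
    from .profile_search import align_to_profile as _impl

    return _impl(profile, seq)


# ---------------------------------------------------------------------------
# translation and ORFs


def six_frame_translate(nt: str) -> list[str]:
    """Translate the three forward and three reverse-complement frames.

    Stops are ``*``; codons containing ``N`` become ``X``; trailing partial
    codons are dropped.  Frames are ordered +1, +2, +3, -1, -2, -3.
    """
    nt = nt.upper()
    if len(nt) < 3:
        raise ValueError("need at least one full codon")
    bad = set(nt) - set("ACGTN")
    if bad:
        raise ValueError(f"illegal nucleotides {bad}")
    frames = []
    rc = str(Seq(nt).reverse_complement())
    for template in (nt, rc):
        for off in range(3):
            sub = template[off:]
            sub = sub[: len(sub) - len(sub) % 3]
            frames.append(str(Seq(sub).translate()) if sub else "")
    return frames


class OrfResult(NamedTuple):
    sequence: str
    found: bool
    frame: int  # 0-based frame index into the six_frame_translate output


def longest_orf(aa_frames: Sequence[str]) -> OrfResult:
    """Longest M-initiated, stop-free segment across the six frames.

    Ties are broken by frame order then leftmost start.  When no frame has
    a methionine-initiated segment the result is empty and flagged.
    """
    best = OrfResult("", False, -1)
    for f, frame in enumerate(aa_frames):
        for part_start, part in _stop_free_parts(frame):
            m = part.find("M")
            if m < 0:
                continue
            orf = part[m:]
            if len(orf) > len(best.sequence):
                best = OrfResult(orf, True, f)
    return best


def _stop_free_parts(frame: str):
    start = 0
    for i, c in enumerate(frame):
        if c == "*":
            if i > start:
                yield start, frame[start:i]
            start = i + 1
    if start < len(frame):
        yield start, frame[start:]


# ---------------------------------------------------------------------------
# non-redundant database construction


def build_nr_database(seqs: Iterable[TaxLabeledSequence]) -> SequenceDatabase:
    """Merge records with identical residue strings into one.

    The surviving record keeps the lexicographically smallest id, unions all
    source ids, and keeps the shared taxonomy labels; records with
    conflicting labels are merged with domain/category ``Unknown`` plus a
    warning.  The operation is idempotent.
    """
    groups: dict[str, list[TaxLabeledSequence]] = {}
    for rec in seqs:
        groups.setdefault(rec.residues, []).append(rec)
    merged = []
    for residues, recs in groups.items():
        recs.sort(key=lambda r: r.id)
        keep = recs[0]
        if len(recs) == 1:
            merged.append(keep)
            continue
        sources = frozenset().union(*(r.source_ids for r in recs))
        domains = {r.domain_of_life for r in recs}
        cats = {r.category for r in recs}
        domain = domains.pop() if len(domains) == 1 else "Unknown"
        cat = cats.pop() if len(cats) == 1 else "Unknown"
        if domain == "Unknown" or cat == "Unknown":
            warnings.warn(
                f"conflicting taxonomy while merging duplicates of {keep.id!r}",
                stacklevel=2,
            )
        merged.append(TaxLabeledSequence(keep.id, residues, domain, cat, sources))
    merged.sort(key=lambda r: r.id)
    return SequenceDatabase(merged)


# ---------------------------------------------------------------------------
# FASTA / TSV I/O


def read_fasta(path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(path, records: Iterable[tuple[str, str]], wrap: int = 60):
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), wrap):
                fh.write(seq[i:i + wrap] + "\n")


def read_alignment_fasta(path) -> Alignment:
    return Alignment(read_fasta(path))


def write_alignment_fasta(path, alignment: Alignment, wrap: int = 60):
    write_fasta(path, alignment.rows, wrap=wrap)


def read_taxonomy_tsv(path) -> dict[str, tuple[str, str]]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str)
    return {row.id: (row.domain_of_life, row.category) for row in df.itertuples()}


def write_taxonomy_tsv(path, taxonomy: dict[str, tuple[str, str]]):
    import pandas as pd

    df = pd.DataFrame(
        [(k, d, c) for k, (d, c) in sorted(taxonomy.items())],
        columns=["id", "domain_of_life", "category"],
    )
    df.to_csv(path, sep="\t", index=False)


def database_from_fasta(fasta_path, taxonomy_path=None) -> SequenceDatabase:
    taxonomy = read_taxonomy_tsv(taxonomy_path) if taxonomy_path else {}
    records = []
    for rid, seq in read_fasta(fasta_path):
        domain, cat = taxonomy.get(rid, ("Unknown", "background"))
        records.append(TaxLabeledSequence(rid, seq, domain, cat))
    return SequenceDatabase(records)
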
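"""Position-specific profile search and per-window taxonomic provenance.

A :class:`ProfileModel` is a simplified profile: per-column log-odds match
scores (bits) with affine gap penalties, built from an alignment with
background-proportional pseudocounts.  It deliberately omits the full
profile-HMM state machine: the discovery logic downstream needs rankings
and hit envelopes, not forward-algorithm posteriors.

E-values are calibrated per profile by fitting a Gumbel law to maximal
local scores on shuffled decoy sequences, giving
``E(s) = database_size * P(max score >= s)``.

The provenance profile is the sliding-window computation: every window of
the source alignment becomes its own profile, is searched against the
database, and the taxonomic origins of its hits are stacked per window.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
from scipy.stats import gumbel_r

from ._kernels import gotoh_profile_global, gotoh_profile_local
from .seqcore import (
    Alignment,
    CHAR_INDEX,
    GAP,
    SequenceDatabase,
    encode_residues,
)
from .substitution import AMINO_ACIDS
from ._lg_data import LG_FREQS

SCORE_FLOOR = -30.0  # bits; cap for log-odds of unobserved residues
DEFAULT_GAP_OPEN_BITS = 4.0
DEFAULT_GAP_EXTEND_BITS = 0.5

PROVENANCE_CATEGORIES = (
    "Bacteria",
    "Archaea",
    "Virus",
    "Eukaryota_focal",
    "Eukaryota_other",
    "Unknown",
)


class CalibrationError(RuntimeError):
    """Raised when decoy scores are degenerate and no Gumbel fit exists."""


class UncalibratedProfileError(RuntimeError):
    """Raised when a search requires E-values but the profile has none."""


class Envelope(NamedTuple):
    """1-based inclusive hit coordinates; ``empty`` envelopes are all-zero."""

    target_start: int
    target_end: int
    profile_start: int
    profile_end: int

    @property
    def empty(self) -> bool:
        return self.target_end == 0


@dataclass
class EValueCalibration:
    location: float
    scale: float
    n_decoys: int

    def sf(self, score: float) -> float:
        return float(gumbel_r.sf(score, loc=self.location, scale=self.scale))


@dataclass
class ProfileModel:
    """Per-column log-odds scoring model built from an alignment."""

    match_scores: np.ndarray  # (n_columns, 21) bits; column 20 is X
    background_freqs: np.ndarray
    gap_open: float = DEFAULT_GAP_OPEN_BITS
    gap_extend: float = DEFAULT_GAP_EXTEND_BITS
    pseudocount_weight: float = 1.0
    source_columns: list = field(default_factory=list)
    calibration: EValueCalibration | None = None

    def __post_init__(self):
        self.match_scores = np.asarray(self.match_scores, dtype=float)
        if self.match_scores.ndim != 2 or self.match_scores.shape[1] != 21:
            raise ValueError("match_scores must have shape (n_columns, 21)")
        if self.n_columns < 1:
            raise ValueError("profile needs at least one column")
        if not np.all(np.isfinite(self.match_scores)):
            raise ValueError("match_scores must be finite")
        bg = np.asarray(self.background_freqs, dtype=float)
        if bg.shape != (20,) or abs(bg.sum() - 1.0) > 1e-9:
            raise ValueError("background_freqs must be 20 values summing to 1")
        self.background_freqs = bg
        if not self.source_columns:
            self.source_columns = list(range(1, self.n_columns + 1))

    @property
    def n_columns(self) -> int:
        return self.match_scores.shape[0]

    @property
    def is_calibrated(self) -> bool:
        return self.calibration is not None


@dataclass
class SearchHit:
    target_id: str
    score: float
    e_value: float
    target_start: int
    target_end: int
    profile_start: int = 0
    profile_end: int = 0

    def __post_init__(self):
        if self.e_value <= 0:
            raise ValueError("e_value must be positive")
        if self.target_start > self.target_end:
            raise ValueError("hit coordinates out of order")


def default_background() -> np.ndarray:
    """Background residue frequencies (LG equilibrium frequencies)."""
    bg = np.asarray(LG_FREQS, dtype=float)
    return bg / bg.sum()


def build_profile(alignment: Alignment, pseudocount_weight: float = 1.0,
                  background_freqs: np.ndarray | None = None,
                  gap_open: float = DEFAULT_GAP_OPEN_BITS,
                  gap_extend: float = DEFAULT_GAP_EXTEND_BITS,
                  min_column_occupancy: float = 0.5) -> ProfileModel:
    """Build a log-odds profile from an alignment.

    Column frequencies are ``(counts + w * background) / (n + w)``;
    match scores are ``log2(freq / background)`` floored at -30 bits.
    Columns with occupancy below ``min_column_occupancy`` are excluded so
    gap-dominated regions do not dilute the model; ``X`` residues count
    toward occupancy but not toward any residue.  The ``X`` score is 0 in
    every column.
    """
    if pseudocount_weight <= 0:
        raise ValueError("pseudocount_weight must be positive")
    bg = default_background() if background_freqs is None else np.asarray(background_freqs, float)
    bg = bg / bg.sum()
    n_cols = alignment.n_columns
    counts = np.zeros((n_cols, 20))
    occupied = np.zeros(n_cols)
    for _, row in alignment.rows:
        for j, c in enumerate(row):
            if c == GAP:
                continue
            occupied[j] += 1
            idx = CHAR_INDEX[c]
            if idx < 20:
                counts[j, idx] += 1
    occ = occupied / alignment.n_rows
    keep = [j for j in range(n_cols) if occ[j] >= min_column_occupancy - 1e-12]
    if not keep:
        raise ValueError("no alignment column meets the occupancy floor")
    counts = counts[keep]
    totals = counts.sum(axis=1, keepdims=True)
    freqs = (counts + pseudocount_weight * bg[None, :]) / (totals + pseudocount_weight)
    scores = np.maximum(np.log2(freqs / bg[None, :]), SCORE_FLOOR)
    match = np.zeros((len(keep), 21))
    match[:, :20] = scores
    return ProfileModel(
        match, bg, gap_open, gap_extend, pseudocount_weight,
        source_columns=[j + 1 for j in keep],
    )


def window_profiles(alignment: Alignment, window_size: int = 60, step: int = 1,
                    min_window_occupancy: float | None = None,
                    **profile_kwargs) -> list[tuple[int, ProfileModel]]:
    """Profiles for sliding windows over the alignment columns.

    Windows start at 1-based columns 1, 1+step, ...; there are exactly
    ``floor((L - w) / step) + 1`` of them.  With ``min_window_occupancy``
    set, windows whose mean occupancy falls below it are dropped.
    """
    length = alignment.n_columns
    if window_size < 1 or step < 1:
        raise ValueError("window_size and step must be positive")
    if window_size > length:
        raise ValueError("window_size exceeds alignment length")
    occ = alignment.occupancy()
    out = []
    for start0 in range(0, length - window_size + 1, step):
        if min_window_occupancy is not None:
            if occ[start0:start0 + window_size].mean() < min_window_occupancy:
                continue
        window = alignment.select_columns(range(start0, start0 + window_size))
        try:
            prof = build_profile(window, **profile_kwargs)
        except ValueError:
            continue  # window entirely gap-dominated
        out.append((start0 + 1, prof))
    return out


def score_profile_local(profile: ProfileModel, seq: str) -> tuple[float, Envelope]:
    """Best local (Smith-Waterman-style) profile-to-sequence segment score.

    The score is never negative; when no segment scores positive the
    envelope is empty.  Ties prefer the smallest start coordinates.
    """
    if not seq:
        raise ValueError("cannot score an empty sequence")
    encoded = encode_residues(seq)
    score, ei, ej, si, sj = gotoh_profile_local(
        profile.match_scores, encoded, profile.gap_open, profile.gap_extend
    )
    if score <= 0.0:
        return 0.0, Envelope(0, 0, 0, 0)
    return float(score), Envelope(sj, ej, si, ei)


def calibrate_evalue(profile: ProfileModel, database: SequenceDatabase,
                     n_decoys: int = 200, seed: int = 0) -> EValueCalibration:
    """Fit Gumbel E-value parameters from shuffled decoy max-scores.

    Decoys are residue-shuffled copies of database sequences (length
    distribution matched by sampling records with replacement).  The fitted
    law gives ``P(max score >= s)``; E-values scale linearly with the size
    of the searched database.  The calibration is attached to the profile.
    """
    if n_decoys < 100:
        raise ValueError("need at least 100 decoys for a stable fit")
    if len(database) == 0:
        raise ValueError("cannot calibrate against an empty database")
    rng = np.random.default_rng(seed)
    scores = np.empty(n_decoys)
    records = database.records
    for k in range(n_decoys):
        rec = records[rng.integers(len(records))]
        residues = np.array(list(rec.residues))
        rng.shuffle(residues)
        scores[k], _ = score_profile_local(profile, "".join(residues))
    if np.ptp(scores) < 1e-9:
        raise CalibrationError("decoy scores are degenerate; cannot fit Gumbel")
    loc, scale = gumbel_r.fit(scores)
    calib = EValueCalibration(float(loc), float(scale), n_decoys)
    profile.calibration = calib
    return calib


def evalue(profile: ProfileModel, score: float, database_size: int) -> float:
    if not profile.is_calibrated:
        raise UncalibratedProfileError("profile has no E-value calibration")
    return max(database_size * profile.calibration.sf(score), 1e-300)


def search_database(profile: ProfileModel, db: SequenceDatabase,
                    e_threshold: float = 0.01) -> list[SearchHit]:
    """All database records with ``E <= e_threshold``, best E first.

    Every record is scored once; ties in E-value are ordered by id.
    """
    if not profile.is_calibrated:
        raise UncalibratedProfileError("calibrate the profile before searching")
    hits = []
    n = len(db)
    for rec in db:
        score, env = score_profile_local(profile, rec.residues)
        e = evalue(profile, score, n)
        if e <= e_threshold:
            hits.append(SearchHit(rec.id, score, e, env.target_start,
                                  env.target_end, env.profile_start, env.profile_end))
    hits.sort(key=lambda h: (h.e_value, h.target_id))
    return hits


@dataclass
class ProvenanceProfile:
    """Per-window stacked counts of hit categories (the stack-plot table)."""

    window_starts: list
    counts: list  # list[dict category -> int], parallel to window_starts
    categories: tuple = PROVENANCE_CATEGORIES

    def totals(self) -> list[int]:
        return [sum(c.values()) for c in self.counts]

    def majority(self, window_index: int, exclude_focal: bool = False,
                 min_hits: int = 1) -> str | None:
        """Category holding a strict majority of the window's hits.

        With ``exclude_focal`` the focal family's own members are left out,
        asking where the window's *other* relatives come from — the
        provenance question proper.  ``min_hits`` guards against calling a
        signal on a window with only a stray hit or two.
        """
        c = dict(self.counts[window_index])
        if exclude_focal:
            c.pop("Eukaryota_focal", None)
        total = sum(c.values())
        if total < max(1, min_hits):
            return None
        top = max(c, key=lambda k: (c[k], k))
        return top if c[top] * 2 > total else None

    def to_dataframe(self):
        import pandas as pd

        rows = [
            {"window_start": s, **{k: c.get(k, 0) for k in self.categories}}
            for s, c in zip(self.window_starts, self.counts)
        ]
        return pd.DataFrame(rows)

    def write_tsv(self, path):
        self.to_dataframe().to_csv(path, sep="\t", index=False)


def hit_category(domain_of_life: str, category: str,
                 focal_category: str = "focal") -> str:
    if domain_of_life == "Eukaryota":
        return "Eukaryota_focal" if category == focal_category else "Eukaryota_other"
    if domain_of_life in ("Bacteria", "Archaea", "Virus"):
        return domain_of_life
    return "Unknown"


def calibrate_windows(windows, db: SequenceDatabase, n_decoys: int = 100,
                      seed: int = 0) -> None:
    """Calibrate every window profile in place (one decoy set per window)."""
    for k, (_, prof) in enumerate(windows):
        calibrate_evalue(prof, db, n_decoys=n_decoys, seed=seed + 7919 * k)


def provenance_profile(windows, db: SequenceDatabase, e_threshold: float = 0.01,
                       focal_category: str = "focal") -> ProvenanceProfile:
    """Count hit taxonomy per sliding window.

    For each calibrated window profile, the database is searched at the
    given E-value threshold and each hit is binned by domain of life, with
    eukaryotes split into focal-category and other.  Counts per window
    always sum to that window's total hits.
    """
    import warnings as _warnings

    starts, counts = [], []
    for start, prof in windows:
        hits = search_database(prof, db, e_threshold)
        tally = {k: 0 for k in PROVENANCE_CATEGORIES}
        for hit in hits:
            rec = db[hit.target_id]
            if rec.domain_of_life not in ("Eukaryota", "Bacteria", "Archaea", "Virus"):
                _warnings.warn(f"unknown domain of life for {rec.id!r}; counted as Unknown")
            tally[hit_category(rec.domain_of_life, rec.category, focal_category)] += 1
        starts.append(start)
        counts.append(tally)
    return ProvenanceProfile(starts, counts)


def reduce_database(db: SequenceDatabase, profiles: Iterable[ProfileModel],
                    e_threshold: float = 10.0) -> SequenceDatabase:
    """Pre-filter: keep records hit by any of the given profiles.

    Mirrors the consolidation of whole-domain search hits into a reduced
    database before the windowed scan, which guards the short windows
    against unrelated false positives.
    """
    keep: dict[str, None] = {}
    for prof in profiles:
        for hit in search_database(prof, db, e_threshold):
            keep[hit.target_id] = None
    return SequenceDatabase([db[i] for i in db.ids if i in keep])


# ---------------------------------------------------------------------------
# profile-to-sequence global alignment (hmmalign-style)


def align_to_profile(profile: ProfileModel, seq: str) -> str:
    """Globally align a sequence to the profile; returns the gapped row.

    The row is in profile coordinates: one character per profile column
    (residue or gap) with inserted residues shown in lower case between the
    columns they follow.  Use :func:`match_columns_row` for the fixed-width
    match-state projection.
    """
    if not seq:
        raise ValueError("cannot align an empty sequence")
    encoded = encode_residues(seq)
    _, state, ptr = gotoh_profile_global(
        profile.match_scores, encoded, profile.gap_open, profile.gap_extend
    )
    i, j = profile.n_columns, len(seq)
    out = []
    while i > 0 or j > 0:
        p = ptr[state, i, j]
        if state == 0:
            out.append(seq[j - 1])
            i -= 1
            j -= 1
        elif state == 1:
            out.append(GAP)
            i -= 1
        else:
            out.append(seq[j - 1].lower())
            j -= 1
        state = p
        if i == 0 and j > 0:
            state = 2
        elif j == 0 and i > 0:
            state = 1
    return "".join(reversed(out))


def match_columns_row(profile: ProfileModel, seq: str) -> str:
    """Profile-aligned row restricted to match columns (inserts dropped)."""
    return "".join(c for c in align_to_profile(profile, seq) if not c.islower())


# ---------------------------------------------------------------------------
# profile serialization


def write_profile_tsv(path, profile: ProfileModel):
    with open(path, "w") as fh:
        fh.write(f"# gap_open={profile.gap_open}\tgap_extend={profile.gap_extend}"
                 f"\tpseudocount_weight={profile.pseudocount_weight}\n")
        if profile.calibration is not None:
            c = profile.calibration
            fh.write(f"# calibration_location={c.location}\tcalibration_scale={c.scale}"
                     f"\tn_decoys={c.n_decoys}\n")
        fh.write("# background=" + ",".join(f"{x:.6f}" for x in profile.background_freqs) + "\n")
        fh.write("column\tsource_column\t" + "\t".join(AMINO_ACIDS) + "\n")
        for k in range(profile.n_columns):
            row = "\t".join(f"{x:.5f}" for x in profile.match_scores[k, :20])
            fh.write(f"{k + 1}\t{profile.source_columns[k]}\t{row}\n")


def read_profile_tsv(path) -> ProfileModel:
    meta = {}
    rows = []
    src = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                for part in line[1:].strip().split("\t"):
                    k, _, v = part.partition("=")
                    meta[k] = v
            elif line and not line.startswith("column\t"):
                fields = line.split("\t")
                src.append(int(fields[1]))
                rows.append([float(x) for x in fields[2:22]])
    match = np.zeros((len(rows), 21))
    match[:, :20] = np.asarray(rows)
    bg = np.array([float(x) for x in meta["background"].split(",")])
    prof = ProfileModel(
        match, bg / bg.sum(),
        float(meta.get("gap_open", DEFAULT_GAP_OPEN_BITS)),
        float(meta.get("gap_extend", DEFAULT_GAP_EXTEND_BITS)),
        float(meta.get("pseudocount_weight", 1.0)),
        source_columns=src,
    )
    if "calibration_location" in meta:
        prof.calibration = EValueCalibration(
            float(meta["calibration_location"]),
            float(meta["calibration_scale"]),
            int(meta.get("n_decoys", 0)),
        )
    return prof
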
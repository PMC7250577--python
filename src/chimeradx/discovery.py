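"""Iterative discovery of two-domain (chimeric) orthologs.

A sequence is an architecture hit when it carries a domain-A hit strictly
N-terminal to a domain-B hit, both at the E-value threshold, with
non-overlapping envelopes.  No length, composition or conservation demand
is placed on the inter-domain linker, which in real chimeras is a
fast-evolving disordered region.  Discovery iterates: build profiles from
the current domain alignments, scan the database, add the new hits' domain
segments to the alignments, and repeat until the accepted set stops
growing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .profile_search import (
    ProfileModel,
    build_profile,
    calibrate_evalue,
    evalue,
    match_columns_row,
    score_profile_local,
)
from .seqcore import Alignment, SequenceDatabase, six_frame_translate, longest_orf


@dataclass
class ArchitectureHit:
    """A sequence carrying domain A strictly N-terminal to domain B."""

    target_id: str
    domainA_span: tuple
    domainB_span: tuple
    linker_span: tuple  # (0, 0) when the domains abut
    domainA_evalue: float
    domainB_evalue: float

    def __post_init__(self):
        a_s, a_e = self.domainA_span
        b_s, b_e = self.domainB_span
        if not (1 <= a_s <= a_e < b_s <= b_e):
            raise ValueError("domain A must lie strictly N-terminal to domain B")

    @property
    def combined_evalue(self):
        return self.domainA_evalue * self.domainB_evalue


@dataclass
class DiscoveryState:
    """State of the iterative search after each round."""

    round: int
    accepted_ids: list
    alignmentA: Alignment
    alignmentB: Alignment
    profileA: ProfileModel
    profileB: ProfileModel
    converged: bool
    rejected_overlaps: list = field(default_factory=list)
    per_round_counts: list = field(default_factory=list)


def find_architecture_hits(db: SequenceDatabase, profileA: ProfileModel,
                           profileB: ProfileModel,
                           e_threshold: float = 0.01) -> list[ArchitectureHit]:
    """Sequences with a profile-A hit strictly N-terminal to a profile-B hit.

    Overlapping envelopes are rejected (recorded, not an error).  Hits are
    sorted by combined E-value, ties by id.
    """
    for prof, name in ((profileA, "A"), (profileB, "B")):
        if not prof.is_calibrated:
            raise ValueError(f"profile {name} is not calibrated")
    hits, _ = _architecture_scan(db, profileA, profileB, e_threshold)
    return hits


def _architecture_scan(db, profileA, profileB, e_threshold):
    hits = []
    rejected = []
    n = len(db)
    for rec in db:
        score_a, env_a = score_profile_local(profileA, rec.residues)
        if env_a.empty:
            continue
        e_a = evalue(profileA, score_a, n)
        if e_a > e_threshold:
            continue
        score_b, env_b = score_profile_local(profileB, rec.residues)
        if env_b.empty:
            continue
        e_b = evalue(profileB, score_b, n)
        if e_b > e_threshold:
            continue
        if env_a.target_end >= env_b.target_start:
            rejected.append((rec.id, "overlapping or out-of-order envelopes"))
            continue
        linker = (env_a.target_end + 1, env_b.target_start - 1)
        if linker[0] > linker[1]:
            linker = (0, 0)  # domains abut: empty linker
        hits.append(ArchitectureHit(
            rec.id,
            (env_a.target_start, env_a.target_end),
            (env_b.target_start, env_b.target_end),
            linker, e_a, e_b,
        ))
    hits.sort(key=lambda h: (h.combined_evalue, h.target_id))
    return hits, rejected


def iterate_discovery(db: SequenceDatabase, seedA: Alignment, seedB: Alignment,
                      e_threshold: float = 0.01, max_rounds: int = 10,
                      n_decoys: int = 100, seed: int = 0,
                      require_order: bool = True) -> DiscoveryState:
    """Iterate profile building and architecture search to a fixed point.

    Convergence means the accepted id set is unchanged between successive
    rounds; the accepted set grows monotonically.  New members contribute
    their domain segments (aligned to the current profiles) to the next
    round's alignments.  ``require_order=False`` relaxes the A-before-B
    architecture demand to co-occurrence for gene families with the
    opposite domain order.
    """
    if seedA.n_rows < 1 or seedB.n_rows < 1:
        raise ValueError("seed alignments must be non-empty")
    alnA, alnB = seedA, seedB
    accepted: dict[str, ArchitectureHit] = {}
    rejected_all = []
    per_round = []
    converged = False
    round_no = 0
    for round_no in range(1, max_rounds + 1):
        profileA = build_profile(alnA)
        profileB = build_profile(alnB)
        calibrate_evalue(profileA, db, n_decoys=n_decoys, seed=seed + 2 * round_no)
        calibrate_evalue(profileB, db, n_decoys=n_decoys, seed=seed + 2 * round_no + 1)
        hits, rejected = _architecture_scan(db, profileA, profileB, e_threshold)
        if not require_order:
            hits = hits + _unordered_hits(db, profileA, profileB, e_threshold,
                                          {h.target_id for h in hits})
        rejected_all.extend(rejected)
        new = [h for h in hits if h.target_id not in accepted]
        for h in hits:
            accepted.setdefault(h.target_id, h)
        per_round.append(len(accepted))
        if not new:
            converged = True
            break
        # grow the alignments with the new members' domain segments (seed
        # rows may already carry some accepted ids)
        rowsA = list(alnA.rows)
        rowsB = list(alnB.rows)
        present = set(alnA.ids)
        for h in (h for h in new if h.target_id not in present):
            rec = db[h.target_id]
            seg_a = rec.residues[h.domainA_span[0] - 1:h.domainA_span[1]]
            seg_b = rec.residues[h.domainB_span[0] - 1:h.domainB_span[1]]
            rowA = match_columns_row(profileA, seg_a)
            rowB = match_columns_row(profileB, seg_b)
            rowsA.append((h.target_id, _fit_width(rowA, profileA, alnA.n_columns)))
            rowsB.append((h.target_id, _fit_width(rowB, profileB, alnB.n_columns)))
        alnA = Alignment(rowsA)
        alnB = Alignment(rowsB)
    return DiscoveryState(
        round=round_no,
        accepted_ids=sorted(accepted),
        alignmentA=alnA,
        alignmentB=alnB,
        profileA=profileA,
        profileB=profileB,
        converged=converged,
        rejected_overlaps=rejected_all,
        per_round_counts=per_round,
    )


def _fit_width(row: str, profile: ProfileModel, width: int) -> str:
    """Expand a match-columns row back to full alignment width.

    Profile columns excluded for low occupancy reappear as gaps so the row
    matches the alignment the profile was built from.
    """
    if len(row) == width:
        return row
    out = ["-"] * width
    for k, col in enumerate(profile.source_columns):
        out[col - 1] = row[k]
    return "".join(out)


def _unordered_hits(db, profileA, profileB, e_threshold, already):
    out = []
    n = len(db)
    for rec in db:
        if rec.id in already:
            continue
        score_a, env_a = score_profile_local(profileA, rec.residues)
        score_b, env_b = score_profile_local(profileB, rec.residues)
        if env_a.empty or env_b.empty:
            continue
        if (evalue(profileA, score_a, n) > e_threshold
                or evalue(profileB, score_b, n) > e_threshold):
            continue
        if env_b.target_end < env_a.target_start:  # B strictly before A
            linker = (env_b.target_end + 1, env_a.target_start - 1)
            if linker[0] > linker[1]:
                linker = (0, 0)
            out.append(ArchitectureHit(
                rec.id,
                (env_b.target_start, env_b.target_end),
                (env_a.target_start, env_a.target_end),
                linker,
                evalue(profileA, score_a, n),
                evalue(profileB, score_b, n),
            ))
    return out


def dedupe_best_per_species(hits, species_of: dict) -> list:
    """Keep, per species, the hit with the lowest (combined) E-value.

    Works for both :class:`ArchitectureHit` and plain search hits; ties are
    broken by target id.
    """
    best: dict[str, object] = {}
    for h in hits:
        if h.target_id not in species_of:
            raise ValueError(f"no species mapping for {h.target_id!r}")
        sp = species_of[h.target_id]
        key = (getattr(h, "combined_evalue", None) or h.e_value, h.target_id)
        cur = best.get(sp)
        if cur is None or key < ((getattr(cur, "combined_evalue", None)
                                  or cur.e_value), cur.target_id):
            best[sp] = h
    return sorted(best.values(), key=lambda h: h.target_id)


def translated_search(nt_records, seedA: Alignment, seedB: Alignment,
                      taxonomy: dict | None = None, **kwargs):
    """Six-frame translated discovery over nucleotide records.

    Each record's frames are reduced to the longest ORF protein; hits are
    reported in protein space with the originating frame recorded.
    """
    from .seqcore import TaxLabeledSequence

    proteins = []
    frames = {}
    for rid, nt in nt_records:
        orf = longest_orf(six_frame_translate(nt))
        if not orf.found:
            continue
        domain, cat = (taxonomy or {}).get(rid, ("Unknown", "background"))
        proteins.append(TaxLabeledSequence(rid, orf.sequence, domain, cat))
        frames[rid] = orf.frame
    db = SequenceDatabase(proteins)
    state = iterate_discovery(db, seedA, seedB, **kwargs)
    return state, frames
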
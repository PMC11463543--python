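"""Sorting-motif scanners and peptide-window extraction.

Two recycling-pathway recognition grammars are implemented:

* SNX27 (PDZ domain): a C-terminal [S/T]-x-Phi motif — serine or
  threonine at the third-to-last position and a hydrophobic residue as
  the very last residue.  An acidic context count (D/E at positions
  -4..-8) is reported because upstream acidity enhances PDZ binding, but
  it is never used as a filter.
* SNX17 (FERM domain): Phi-x-N-x-x-[Y/F] anywhere in the scanned region
  (optionally restricted to the cytosolic tail downstream of the last
  transmembrane segment).  Only the literal grammar is scanned; looser
  "related motif" variants are deliberately not expanded.

Phi is the Kyte-Doolittle-positive hydrophobic set {A,V,L,I,M,F,W,Y},
exposed as a module constant so sensitivity to its definition can be
tested.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .io import ProteinSequence

log = logging.getLogger("endolyso")

#: hydrophobic residue set (Phi) for both grammars
HYDROPHOBIC = frozenset("AVLIMFWY")
ACIDIC = frozenset("DE")

#: peptide window length presented to the complex predictor
PEPTIDE_WINDOW = 15


@dataclass(frozen=True)
class MotifHit:
    """A located sorting-motif match (1-based inclusive coordinates)."""

    protein: str
    motif_type: str  # "SNX27" | "SNX17"
    start: int
    end: int
    matched: str
    c_terminal: bool = False
    acidic_context: int = 0


@dataclass(frozen=True)
class PeptideQuery:
    """A peptide window to be scored against a sorting-nexin domain."""

    protein: str
    motif_type: str
    peptide: str
    window: tuple[int, int]  # 1-based inclusive
    role: str = "candidate"  # "candidate" | "control"
    short: bool = False

    def key(self) -> tuple[str, str, str]:
        return (self.protein, self.motif_type, self.peptide)


def scan_snx27(s: ProteinSequence, hydrophobic: frozenset[str] = HYDROPHOBIC
               ) -> MotifHit | None:
    """Scan the C-terminus for an [S/T]-x-Phi PDZ-binding motif."""
    L = len(s.seq)
    if L < 3:
        log.info("[motifs] %s shorter than 3 residues; SNX27 scan skipped", s.id)
        return None
    if s.seq[-3] not in "ST" or s.seq[-1] not in hydrophobic:
        return None
    context = s.seq[max(0, L - 8):L - 3]  # positions -4..-8, clipped
    return MotifHit(
        protein=s.id, motif_type="SNX27", start=L - 2, end=L,
        matched=s.seq[-3:], c_terminal=True,
        acidic_context=sum(1 for r in context if r in ACIDIC),
    )


def scan_snx17(s: ProteinSequence, region: str = "full",
               hydrophobic: frozenset[str] = HYDROPHOBIC) -> list[MotifHit]:
    """Scan for Phi-x-N-x-x-[Y/F] FERM-binding motifs.

    Every start position is checked, so overlapping matches with distinct
    starts are all reported.  With ``region="cytosolic_tail"`` the scan is
    restricted to residues after the last transmembrane span; without
    topology it falls back to the full sequence with a warning.
    """
    if region not in ("full", "cytosolic_tail"):
        raise ValueError(f"unknown region {region!r}")
    offset = 0
    if region == "cytosolic_tail":
        if s.topology:
            offset = s.topology[-1][1]  # first residue after the last TM span
        else:
            log.warning("[motifs] %s has no topology; scanning full sequence", s.id)
    seq = s.seq[offset:]
    hits = []
    for i in range(len(seq) - 5):
        w = seq[i:i + 6]
        if w[0] in hydrophobic and w[2] == "N" and w[5] in "YF":
            hits.append(MotifHit(
                protein=s.id, motif_type="SNX17",
                start=offset + i + 1, end=offset + i + 6, matched=w,
            ))
    return hits


def extract_peptides(hits: list[MotifHit], sequences: dict[str, ProteinSequence],
                     role: str = "candidate") -> list[PeptideQuery]:
    """Extract the predictor peptide window for each motif hit.

    SNX27 hits yield the C-terminal 15-mer (the whole sequence, flagged
    short, for proteins under 15 residues).  SNX17 hits yield a 15-mer
    with 4 residues upstream and 5 downstream of the 6-residue motif,
    shifted inward at the termini so the motif is always fully contained.
    """
    out = []
    for h in hits:
        if h.protein not in sequences:
            raise KeyError(f"hit references unknown protein {h.protein}")
        seq = sequences[h.protein].seq
        L = len(seq)
        if not (1 <= h.start <= h.end <= L):
            raise ValueError(f"hit coordinates {h.start}-{h.end} out of bounds "
                             f"for {h.protein} (length {L})")
        if h.motif_type == "SNX27":
            start0 = max(0, L - PEPTIDE_WINDOW)
            out.append(PeptideQuery(
                protein=h.protein, motif_type="SNX27", peptide=seq[start0:],
                window=(start0 + 1, L), role=role, short=L < PEPTIDE_WINDOW))
        elif h.motif_type == "SNX17":
            if L <= PEPTIDE_WINDOW:
                out.append(PeptideQuery(
                    protein=h.protein, motif_type="SNX17", peptide=seq,
                    window=(1, L), role=role, short=L < PEPTIDE_WINDOW))
                continue
            start0 = min(max(h.start - 1 - 4, 0), L - PEPTIDE_WINDOW)
            out.append(PeptideQuery(
                protein=h.protein, motif_type="SNX17",
                peptide=seq[start0:start0 + PEPTIDE_WINDOW],
                window=(start0 + 1, start0 + PEPTIDE_WINDOW), role=role))
        else:
            raise ValueError(f"unknown motif type {h.motif_type!r}")
    return out


def c_terminal_peptide(s: ProteinSequence, role: str = "control",
                       motif_type: str = "SNX27") -> PeptideQuery:
    """The C-terminal 15-mer of a protein as a screening query."""
    L = len(s.seq)
    start0 = max(0, L - PEPTIDE_WINDOW)
    return PeptideQuery(protein=s.id, motif_type=motif_type, peptide=s.seq[start0:],
                        window=(start0 + 1, L), role=role, short=L < PEPTIDE_WINDOW)


@dataclass
class ScreenSets:
    """Candidate and control query sets for the two sorting-nexin screens."""

    snx27_candidates: list[PeptideQuery]
    snx27_controls: list[PeptideQuery]
    snx17_candidates: list[PeptideQuery]


def build_screen_sets(snx27_hits: list[MotifHit], snx17_hits: list[MotifHit],
                      sequences: dict[str, ProteinSequence]) -> ScreenSets:
    """Assemble candidate and control peptide sets from scanner output.

    SNX27 candidates are the C-terminal windows of proteins with a PDZ
    motif; the controls are C-termini of proteins carrying an SNX17 motif
    but *no* SNX27 motif, so the control set is disjoint from the
    candidates by protein.  SNX17 candidates are every FERM-motif window.
    """
    with27 = {h.protein for h in snx27_hits}
    with17 = {h.protein for h in snx17_hits}
    if not with27 and not with17:
        log.warning("[motifs] no motif hits; screen sets are empty")
    snx27_candidates = extract_peptides(snx27_hits, sequences, role="candidate")
    controls = [c_terminal_peptide(sequences[p]) for p in sorted(with17 - with27)]
    snx17_candidates = extract_peptides(snx17_hits, sequences, role="candidate")
    return ScreenSets(snx27_candidates=snx27_candidates,
                      snx27_controls=controls,
                      snx17_candidates=snx17_candidates)
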
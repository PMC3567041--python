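"""In-silico terminal restriction fragment prediction.

Given an SSU rRNA gene sequence, locate the (degenerate, IUPAC-coded)
labeled forward primer and the first downstream restriction site, and
report the predicted terminal fragment length. The labeled fragment
retains the fluorescently tagged primer, so lengths count from the
primer 5' end through the cut point. HaeIII recognizes GGCC and cuts
bluntly between the two Gs and two Cs (GG^CC: cut offset 2).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

#: General bacterial forward primer 27F-B (5' FAM label).
PRIMER_27F_B = "AGRGTTYGATYMTGGCTCAG"

IUPAC: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "M": frozenset("AC"), "K": frozenset("GT"),
    "S": frozenset("CG"), "W": frozenset("AT"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"), "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}


@dataclass
class DigestPrediction:
    """Predicted terminal fragment for one sequence.

    Coordinates are 0-based on the scanned strand; ``predicted_trf_bp``
    is the 1-based biological fragment length (primer 5' end through the
    cut point). An ambiguous base in the *sequence* (e.g. N) matches no
    primer position and costs a mismatch.
    """

    sequence_id: str
    status: str  # "ok" | "no_primer" | "no_cut_site"
    orientation: str = "forward"  # strand on which the primer was found
    primer_match_start: int | None = None
    cut_position: int | None = None
    predicted_trf_bp: int | None = None


def _check_primer(primer: str) -> str:
    primer = primer.upper()
    bad = sorted({c for c in primer if c not in IUPAC})
    if bad:
        raise ValueError(f"invalid IUPAC code(s) in primer: {bad}")
    return primer


def find_primer(sequence: str, primer_iupac: str, max_mismatches: int = 0) -> int | None:
    """Leftmost position where the degenerate primer matches the sequence.

    A primer position matches when its IUPAC set contains the sequence
    base; up to ``max_mismatches`` positions may fail. Returns None when
    no window qualifies.
    """
    primer = _check_primer(primer_iupac)
    seq = sequence.upper()
    sets = [IUPAC[c] for c in primer]
    L = len(primer)
    for start in range(0, len(seq) - L + 1):
        mismatches = 0
        for offset, allowed in enumerate(sets):
            if seq[start + offset] not in allowed:
                mismatches += 1
                if mismatches > max_mismatches:
                    break
        else:
            return start
    return None


def predict_trf(
    sequence: str,
    primer_iupac: str = PRIMER_27F_B,
    enzyme_recognition: str = "GGCC",
    cut_offset: int = 2,
    max_mismatches: int = 0,
    search_reverse: bool = True,
    sequence_id: str = "",
) -> DigestPrediction:
    """Predict the labeled terminal fragment length of one sequence.

    The restriction-site search starts at the primer match itself, so a
    site overlapping the primer 3' end is counted. When the forward scan
    finds no primer and ``search_reverse`` is set, the reverse
    complement is scanned (clones insert in either orientation) and
    coordinates are reported on that strand.
    """
    seq = sequence.upper()
    for strand, s in (("forward", seq), ("reverse", str(Seq(seq).reverse_complement()))):
        start = find_primer(s, primer_iupac, max_mismatches)
        if start is None:
            if strand == "forward" and search_reverse:
                continue
            return DigestPrediction(sequence_id, status="no_primer")
        site = s.find(enzyme_recognition.upper(), start)
        if site < 0:
            return DigestPrediction(
                sequence_id, status="no_cut_site", orientation=strand,
                primer_match_start=start,
            )
        cut = site + cut_offset
        return DigestPrediction(
            sequence_id, status="ok", orientation=strand,
            primer_match_start=start, cut_position=cut,
            predicted_trf_bp=cut - start,
        )
    return DigestPrediction(sequence_id, status="no_primer")


def digest_fasta(
    path, primer_iupac: str = PRIMER_27F_B, enzyme_recognition: str = "GGCC",
    cut_offset: int = 2, max_mismatches: int = 0,
) -> list[DigestPrediction]:
    """Run :func:`predict_trf` over every record of a FASTA file."""
    return [
        predict_trf(
            str(rec.seq), primer_iupac, enzyme_recognition, cut_offset,
            max_mismatches, sequence_id=rec.id,
        )
        for rec in SeqIO.parse(path, "fasta")
    ]


def predictions_to_dataframe(predictions: Sequence[DigestPrediction]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "id": p.sequence_id,
                "orientation": p.orientation,
                "primer_offset": p.primer_match_start,
                "predicted_trf_bp": p.predicted_trf_bp,
                "status": p.status,
            }
            for p in predictions
        ]
    )


def match_trf_to_lineages(
    trfs: Iterable[int | float],
    lineage_table: pd.DataFrame | Iterable[tuple],
    tolerance_bp: int = 1,
) -> dict[int, list[str]]:
    """Map T-RF lengths (predicted or empirical) to candidate lineages.

    ``lineage_table`` holds (lineage, T-RF bp) rows — a DataFrame with
    ``lineage``/``trf_bp`` columns (see :func:`trflp.datasets.common_trf_lineages`)
    or an iterable of (lineage, bp) / (lineage, [bp, ...]) tuples. Each
    query maps to every lineage within ``tolerance_bp`` (empirical
    fragment sizes drift by a base pair or so against predictions);
    unmatched queries map to an empty list. Polyphyletic fragments
    return several lineages.
    """
    if isinstance(lineage_table, pd.DataFrame):
        pairs = list(zip(lineage_table["lineage"], lineage_table["trf_bp"]))
    else:
        pairs = []
        for lineage, bp in lineage_table:
            if isinstance(bp, (list, tuple, set)):
                pairs.extend((lineage, b) for b in bp)
            else:
                pairs.append((lineage, bp))

    out: dict[int, list[str]] = {}
    for q in trfs:
        q = int(q)
        hits = []
        for lineage, bp in pairs:
            if abs(int(bp) - q) <= tolerance_bp and lineage not in hits:
                hits.append(lineage)
        out[q] = hits
    return out
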
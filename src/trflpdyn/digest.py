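"""In-silico T-RFLP of cloned marker-gene amplicons.

Each clone carries one amplicon; after digestion with a restriction enzyme the
fluorescently labeled terminal fragment runs from the 5' labeled base (the
first base of the forward primer) through the base preceding the first cut.
TaqI recognizes TCGA and cleaves between T and C (T^CGA), so the terminal
fragment length is the 0-based index of the first TCGA occurrence plus one.
An amplicon with no recognition site stays uncut and its full length is
reported.

The default primers target the amoA gene (ammonia monooxygenase subunit A),
the standard marker for ammonia-oxidizing bacteria: amoA-1F
(GGGGTTTCTACTGGTGGT, labeled) and amoA-2R (CCCCTCKGSAAAGCCTTCTTC, degenerate
positions in IUPAC code).  Clones may arrive in either orientation;
:func:`orient_by_primer` finds the labeled primer on either strand (IUPAC
aware, one mismatch allowed for PCR errors) and rewrites the amplicon 5'->3'
from its first base.

Predicted lengths are matched to observed fingerprint bins within a tolerance
(default +/-3 bp, the midpoint of the 1-7 bp discrepancy commonly reported
between in-silico and capillary-observed fragment sizes).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from Bio import SeqIO
from Bio.Seq import Seq

FORWARD_PRIMER = "GGGGTTTCTACTGGTGGT"  # amoA-1F (5'-labeled)
REVERSE_PRIMER = "CCCCTCKGSAAAGCCTTCTTC"  # amoA-2R
TAQI_SITE = "TCGA"
TAQI_CUT_OFFSET = 1  # T^CGA

IUPAC = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "R": {"A", "G"}, "Y": {"C", "T"}, "S": {"G", "C"}, "W": {"A", "T"},
    "K": {"G", "T"}, "M": {"A", "C"},
    "B": {"C", "G", "T"}, "D": {"A", "G", "T"},
    "H": {"A", "C", "T"}, "V": {"A", "C", "G"},
    "N": {"A", "C", "G", "T"},
}


@dataclass
class CloneSequence:
    clone_id: str
    sequence: str

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - set(IUPAC)
        if bad:
            raise ValueError(
                f"clone {self.clone_id!r}: non-IUPAC characters {sorted(bad)}"
            )


@dataclass
class DigestResult:
    clone_id: str
    orientation: str  # "forward" | "reverse-complemented"
    predicted_trf: int
    cut_found: bool
    matched_bin: int | None = None
    offset_bp: int | None = None  # predicted - matched


def _bases_compatible(a: str, b: str) -> bool:
    return not IUPAC[a].isdisjoint(IUPAC[b])


def _find_primer(seq: str, primer: str, max_mismatches: int) -> int | None:
    """Leftmost start of an IUPAC-aware primer match with <= max_mismatches."""
    lp = len(primer)
    for start in range(len(seq) - lp + 1):
        mismatches = 0
        for a, b in zip(seq[start : start + lp], primer):
            if not _bases_compatible(a, b):
                mismatches += 1
                if mismatches > max_mismatches:
                    break
        else:
            return start
    return None


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def orient_by_primer(
    clone: CloneSequence,
    fwd_primer: str = FORWARD_PRIMER,
    rev_primer: str = REVERSE_PRIMER,
    max_mismatches: int = 1,
) -> tuple[str, str]:
    """Locate the labeled forward primer and return (amplicon, orientation).

    The amplicon is written 5'->3' starting at the forward primer's first
    base; when the reverse primer's binding site is found downstream the
    amplicon ends with it, otherwise it runs to the end of the sequence.
    """
    if len(clone.sequence) <= max(len(fwd_primer), len(rev_primer)):
        raise ValueError(f"clone {clone.clone_id!r}: sequence shorter than primers")
    hits = {}
    for orient, seq in (
        ("forward", clone.sequence),
        ("reverse-complemented", reverse_complement(clone.sequence)),
    ):
        pos = _find_primer(seq, fwd_primer, max_mismatches)
        if pos is not None:
            hits[orient] = (seq, pos)
    if not hits:
        raise ValueError(
            f"clone {clone.clone_id!r}: forward primer not found on either strand"
        )
    if len(hits) == 2:
        raise ValueError(
            f"clone {clone.clone_id!r}: forward primer found on both strands "
            "(ambiguous orientation)"
        )
    orientation, (seq, start) = next(iter(hits.items()))
    amplicon = seq[start:]
    rc_rev = reverse_complement(rev_primer)
    rev_pos = _find_primer(amplicon[len(fwd_primer):], rc_rev, max_mismatches)
    if rev_pos is not None:
        amplicon = amplicon[: len(fwd_primer) + rev_pos + len(rc_rev)]
    return amplicon, orientation


def predict_trf(
    amplicon: str,
    enzyme_site: str = TAQI_SITE,
    cut_offset: int = TAQI_CUT_OFFSET,
    clone_id: str = "",
) -> tuple[int, bool]:
    """Terminal fragment length from the first exact recognition site.

    Returns (predicted_trf, cut_found).  A window containing degenerate bases
    is counted only if every IUPAC expansion of it equals the site
    (conservative); windows that merely *could* match trigger a warning and
    are not counted.
    """
    amplicon = amplicon.upper()
    ls = len(enzyme_site)
    possible_only: list[int] = []

    def _warn_ambiguous() -> None:
        if possible_only:
            warnings.warn(
                f"clone {clone_id!r}: degenerate base(s) make candidate site(s) at "
                f"{possible_only} ambiguous; treated as uncut there",
                stacklevel=3,
            )

    for i in range(len(amplicon) - ls + 1):
        window = amplicon[i : i + ls]
        # certain site: every IUPAC expansion of the window contains the site
        if all(IUPAC[a] <= IUPAC[b] for a, b in zip(window, enzyme_site)):
            _warn_ambiguous()
            return i + cut_offset, True
        if all(_bases_compatible(a, b) for a, b in zip(window, enzyme_site)):
            possible_only.append(i)
    _warn_ambiguous()
    return len(amplicon), False


def assign_clones(
    results: list[DigestResult],
    bins: list[int],
    tolerance_bp: int = 3,
) -> list[DigestResult]:
    """Match each predicted fragment to the nearest observed bin within tolerance.

    Ties (two bins equally near) break toward the smaller bin with a warning;
    clones with no bin within tolerance stay unmatched (``matched_bin`` None).
    """
    if not bins:
        raise ValueError("bins must be non-empty")
    bins = sorted(bins)
    for res in results:
        dists = [abs(res.predicted_trf - b) for b in bins]
        best = min(dists)
        if best > tolerance_bp:
            res.matched_bin = None
            res.offset_bp = None
            continue
        nearest = [b for b, d in zip(bins, dists) if d == best]
        if len(nearest) > 1:
            warnings.warn(
                f"clone {res.clone_id!r}: predicted {res.predicted_trf} bp is "
                f"equidistant from bins {nearest}; assigning the smaller",
                stacklevel=2,
            )
        res.matched_bin = nearest[0]
        res.offset_bp = res.predicted_trf - nearest[0]
    return results


def digest_clone(
    clone: CloneSequence,
    enzyme_site: str = TAQI_SITE,
    cut_offset: int = TAQI_CUT_OFFSET,
    **orient_kwargs,
) -> DigestResult:
    """Orient one clone by the labeled primer and predict its terminal fragment."""
    amplicon, orientation = orient_by_primer(clone, **orient_kwargs)
    trf, cut = predict_trf(amplicon, enzyme_site, cut_offset, clone_id=clone.clone_id)
    return DigestResult(clone.clone_id, orientation, trf, cut)


def read_clones(path) -> list[CloneSequence]:
    """Read clone sequences from FASTA."""
    return [CloneSequence(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def digest_clones(
    clones: list[CloneSequence],
    bins: list[int] | None = None,
    *,
    enzyme_site: str = TAQI_SITE,
    cut_offset: int = TAQI_CUT_OFFSET,
    tolerance_bp: int = 3,
    **orient_kwargs,
) -> list[DigestResult]:
    """Digest a clone library and (optionally) assign fragments to observed bins."""
    results = [
        digest_clone(c, enzyme_site, cut_offset, **orient_kwargs) for c in clones
    ]
    if bins:
        assign_clones(results, bins, tolerance_bp)
    return results


def results_table(results: list[DigestResult]):
    """DigestResults as a DataFrame (clone_id, orientation, predicted_trf, ...)."""
    import pandas as pd

    return pd.DataFrame(
        [
            dict(
                clone_id=r.clone_id,
                orientation=r.orientation,
                predicted_trf=r.predicted_trf,
                cut_found=r.cut_found,
                matched_bin=r.matched_bin,
                offset_bp=r.offset_bp,
            )
            for r in results
        ]
    )
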
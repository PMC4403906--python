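"""Coding-consequence prediction for candidate variants.

Applies cDNA edits to a coding sequence, translates with the standard genetic
code, classifies the protein-level consequence (synonymous, missense,
frameshift, in-frame indel, stop gain), and performs exact-match in-silico PCR
on a transcript template.

Frameshift notation follows the compact convention used in livestock genetics
reports: ``p.L258fs16`` means the wild-type residue at position 258 is the
first changed one and the premature termination codon is the 16th codon from
there inclusive (PTC at 258 + 16 - 1 = 273). Strict HGVS
(``p.Leu258fs*16``-style, counting the stop as *N with the first novel
residue as 1) is available via ``hgvs_style=True``; the two conventions differ
in how the stop is counted.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

from Bio.Seq import Seq

_NT = set("ACGT")


# ---------------------------------------------------------------------------
# transcript model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TranscriptModel:
    """Exon structure of one transcript with CDS bounds in transcript coordinates.

    Exons are genomic, 1-based closed intervals ordered 5'->3' on the
    transcript (i.e. descending genomic position for minus-strand models).
    ``cds_start``/``cds_end`` are 1-based positions within the spliced
    transcript.
    """

    transcript_id: str
    chrom: str
    strand: str  # "+" or "-"
    exons: tuple  # ((start, end), ...) genomic, closed
    cds_start: int
    cds_end: int

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        spans = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if s2 <= e1:
                raise ValueError("exons overlap")
        length = sum(e - s + 1 for s, e in self.exons)
        if not 1 <= self.cds_start < self.cds_end <= length:
            raise ValueError("CDS bounds outside transcript")

    @property
    def transcript_length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)

    def genomic_to_transcript(self, pos: int) -> int:
        """Map a genomic position inside an exon to 1-based transcript coordinates."""
        offset = 0
        for s, e in self.exons:
            if s <= pos <= e:
                within = (pos - s) if self.strand == "+" else (e - pos)
                return offset + within + 1
            offset += e - s + 1
        raise ValueError(f"position {pos} not exonic in {self.transcript_id}")

    def genomic_to_cdna(self, pos: int) -> int:
        """Map a genomic position to 1-based cDNA (CDS-relative) coordinates."""
        t = self.genomic_to_transcript(pos)
        c = t - self.cds_start + 1
        if c < 1 or t > self.cds_end:
            raise ValueError(f"position {pos} outside the CDS of {self.transcript_id}")
        return c

    def cds_sequence(self, transcript_seq: str) -> str:
        return transcript_seq[self.cds_start - 1 : self.cds_end]


# ---------------------------------------------------------------------------
# sequence edits
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SequenceEdit:
    """A replacement of [start, end] (1-based, closed) by an inserted string.

    ``deleted`` may be empty (pure insertion after position ``start``);
    ``inserted`` may be empty (pure deletion). When ``deleted`` is non-empty
    it is verified against the reference at application time.
    """

    start: int
    end: int
    deleted: str = ""
    inserted: str = ""
    coord_system: str = "cdna"

    def __post_init__(self) -> None:
        if self.coord_system not in ("cdna", "genomic"):
            raise ValueError("coord_system must be 'cdna' or 'genomic'")
        if self.deleted and len(self.deleted) != self.end - self.start + 1:
            raise ValueError("deleted sequence length does not match interval")

    @property
    def length_change(self) -> int:
        deleted_len = (self.end - self.start + 1) if (self.deleted or self.end >= self.start) else 0
        return len(self.inserted) - deleted_len


_HGVS_C = re.compile(
    r"^c\.(?P<start>\d+)(?:_(?P<end>\d+))?"
    r"(?:(?P<sub>(?P<ref>[ACGT])>(?P<alt>[ACGT]))"
    r"|del(?P<del>[ACGT]*)(?:ins(?P<ins>[ACGT]+))?"
    r"|ins(?P<insonly>[ACGT]+))$"
)


def parse_cdna_edit(notation: str) -> SequenceEdit:
    """Parse compact cDNA notation: substitutions, del, delins and ins.

    Examples: ``c.55C>T``, ``c.772_779delTTGAAAAGinsCATC``, ``c.10_12del``,
    ``c.10_11insGGG``.
    """
    m = _HGVS_C.match(notation.strip())
    if not m:
        raise ValueError(f"cannot parse cDNA edit: {notation!r}")
    start = int(m.group("start"))
    end = int(m.group("end")) if m.group("end") else start
    if m.group("sub"):
        return SequenceEdit(start, start, m.group("ref"), m.group("alt"))
    if m.group("insonly"):
        if end != start + 1:
            raise ValueError("insertion requires flanking positions n_n+1")
        # insertion between start and end: model as zero-length replacement
        return SequenceEdit(start + 1, start, "", m.group("insonly"))
    return SequenceEdit(start, end, m.group("del") or "", m.group("ins") or "")


def apply_cdna_edit(cds: str, edit: SequenceEdit) -> str:
    """Apply a cDNA-coordinate edit, validating any stated deleted sequence."""
    cds = cds.upper()
    if edit.coord_system != "cdna":
        raise ValueError("edit must be in cDNA coordinates")
    if edit.end >= edit.start:  # replacement/deletion
        if edit.end > len(cds):
            raise ValueError("edit interval beyond CDS end")
        found = cds[edit.start - 1 : edit.end]
        if edit.deleted and found != edit.deleted.upper():
            raise ValueError(
                f"deleted sequence mismatch at c.{edit.start}_{edit.end}: "
                f"expected {edit.deleted.upper()}, found {found}"
            )
        return cds[: edit.start - 1] + edit.inserted.upper() + cds[edit.end :]
    # pure insertion encoded as (start=n+1, end=n)
    return cds[: edit.end] + edit.inserted.upper() + cds[edit.end :]


# ---------------------------------------------------------------------------
# translation
# ---------------------------------------------------------------------------


def translate_cds(cds: str) -> str:
    """Translate with the standard code, stopping at the first stop codon."""
    cds = cds.upper()
    if set(cds) - _NT:
        bad = sorted(set(cds) - _NT)
        raise ValueError(f"non-ACGT characters in CDS: {bad}")
    if not cds.startswith("ATG"):
        warnings.warn("CDS does not start with ATG", stacklevel=2)
    if len(cds) % 3:
        warnings.warn("trailing partial codon ignored", stacklevel=2)
        cds = cds[: len(cds) - len(cds) % 3]
    aa = str(Seq(cds).translate())
    stop = aa.find("*")
    return aa if stop < 0 else aa[:stop]


def _full_translation(cds: str) -> str:
    """Codon-wise translation without stopping (stop codons as '*')."""
    cds = cds.upper()
    cds = cds[: len(cds) - len(cds) % 3]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return str(Seq(cds).translate())


# ---------------------------------------------------------------------------
# consequence classification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ProteinConsequence:
    consequence: str  # synonymous | missense | frameshift | inframe_indel | stop_gain
    notation: str
    ptc_position: int | None
    wt_length: int
    mut_length: int

    @property
    def length_change(self) -> int:
        return self.mut_length - self.wt_length


def _first_difference(a: str, b: str) -> int | None:
    """1-based index of the first differing residue, None if one is a prefix."""
    for i, (x, y) in enumerate(zip(a, b)):
        if x != y:
            return i + 1
    if len(a) != len(b):
        return min(len(a), len(b)) + 1
    return None


def _compare_translations(wt_cds: str, mut_cds: str, hgvs_style: bool) -> ProteinConsequence:
    wt_pep = translate_cds(wt_cds)
    wt_full = _full_translation(wt_cds)
    if "*" in wt_full[:-1]:
        raise ValueError("wild-type CDS contains an internal stop codon")
    mut_full = _full_translation(mut_cds)
    mut_stop = mut_full.find("*")
    mut_pep = mut_full if mut_stop < 0 else mut_full[:mut_stop]
    ptc = mut_stop + 1 if 0 <= mut_stop < len(wt_pep) else None
    shift = (len(mut_cds) - len(wt_cds)) % 3

    if mut_pep == wt_pep:
        return ProteinConsequence("synonymous", "p.=", None, len(wt_pep), len(mut_pep))

    diff = _first_difference(wt_pep, mut_pep)
    wt_aa = wt_pep[diff - 1] if diff and diff <= len(wt_pep) else ""

    if shift != 0:
        # frameshift: count from first changed residue through the stop
        if mut_stop < 0:
            notation = f"p.{wt_aa}{diff}fs?"
            ptc_out = None
        else:
            ptc_out = mut_stop + 1
            if hgvs_style:
                notation = f"p.{wt_aa}{diff}fs*{ptc_out - diff + 1}"
            else:
                notation = f"p.{wt_aa}{diff}fs{ptc_out - diff + 1}"
        return ProteinConsequence("frameshift", notation, ptc_out, len(wt_pep), len(mut_pep))

    if len(mut_cds) == len(wt_cds):
        if ptc is not None and len(mut_pep) < len(wt_pep):
            return ProteinConsequence(
                "stop_gain", f"p.{wt_aa}{diff}*", ptc, len(wt_pep), len(mut_pep)
            )
        mut_aa = mut_pep[diff - 1] if diff <= len(mut_pep) else "*"
        return ProteinConsequence(
            "missense", f"p.{wt_aa}{diff}{mut_aa}", None, len(wt_pep), len(mut_pep)
        )

    n_res = (len(mut_cds) - len(wt_cds)) // 3
    sign = "ins" if n_res > 0 else "del"
    if ptc is not None and len(mut_pep) < min(len(wt_pep), len(wt_pep) + n_res):
        return ProteinConsequence(
            "stop_gain", f"p.{wt_aa}{diff}*", ptc, len(wt_pep), len(mut_pep)
        )
    return ProteinConsequence(
        "inframe_indel",
        f"p.{wt_aa}{diff}{sign}{abs(n_res)}",
        None,
        len(wt_pep),
        len(mut_pep),
    )


def classify_consequence(
    wt_cds: str, edit: SequenceEdit, hgvs_style: bool = False
) -> ProteinConsequence:
    """Classify the protein consequence of a cDNA edit on a clean wild-type CDS."""
    mut_cds = apply_cdna_edit(wt_cds, edit)
    return _compare_translations(wt_cds, mut_cds, hgvs_style)


def classify_transcript_variant(
    wt_cds: str, variant_cds: str, hgvs_style: bool = False
) -> ProteinConsequence:
    """Classify an observed aberrant transcript against the wild-type CDS.

    Used for transcript variants recovered from RT-PCR subcloning (aberrant
    splice products): distinguishes in-frame insertions (no premature stop,
    reporting the inserted-residue count) from frameshifts with a premature
    termination codon located by translation.
    """
    return _compare_translations(wt_cds, variant_cds, hgvs_style)


# ---------------------------------------------------------------------------
# in-silico PCR
# ---------------------------------------------------------------------------


def in_silico_pcr(template: str, fwd_primer: str, rev_primer: str) -> list[int]:
    """Exact-match amplicon lengths for a primer pair on a template.

    The forward primer must match the template; the reverse complement of the
    reverse primer must match downstream of the forward site. Amplicon length
    is (end of reverse site) - (start of forward site) + 1. All products are
    reported; no product yields an empty list.
    """
    template = template.upper()
    fwd = fwd_primer.upper()
    rev_site = str(Seq(rev_primer.upper()).reverse_complement())
    if len(fwd) < 15 or len(rev_primer) < 15:
        raise ValueError("primers must be at least 15 nt")

    def _find_all(seq: str, sub: str) -> list[int]:
        out, i = [], seq.find(sub)
        while i >= 0:
            out.append(i)
            i = seq.find(sub, i + 1)
        return out

    products = []
    for f in _find_all(template, fwd):
        for r in _find_all(template, rev_site):
            if r >= f + len(fwd):
                products.append(r + len(rev_site) - f)
    return sorted(products)


# ---------------------------------------------------------------------------
# synthetic GLUT2 reference (worked example)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Glut2Reference:
    """Synthetic stand-in for the bovine SLC2A2 (GLUT2) reference transcript.

    This is NOT the RefSeq record (NM_001103222): it is a programmatically
    constructed synthetic CDS/mRNA engineered to reproduce the published
    arithmetic of the bovine GLUT2 frameshift allele so that the consequence
    machinery can be exercised end-to-end without redistributing reference
    data. It satisfies, by construction:

    * 522-residue wild-type protein (1569 nt CDS incl. stop), Pro at 19,
      Leu at 258;
    * the octamer TTGAAAAG at c.772-779, whose replacement by CATC (net -4 nt)
      shifts the frame from residue 258 and terminates at codon 273
      (p.L258fs16), truncating the protein by 250 residues;
    * a single 370 bp product for the exon-6/exon-8 RT-PCR primer pair.

    Note the published cDNA anchor for this delins is one base 5' of the
    anchor used here; only the c.772-779 placement is consistent with the
    published protein-level arithmetic (see the methods note).
    """

    cds: str
    mrna: str
    utr5: str
    utr3: str
    edit: SequenceEdit
    fwd_primer: str
    rev_primer: str


GLUT2_FWD_PRIMER = "CCTGGGCAATCACGAGCTAT"
GLUT2_REV_PRIMER = "TCCAGCTGTCTGGAAAATGC"
GLUT2_EDIT_NOTATION = "c.772_779delTTGAAAAGinsCATC"


def build_glut2_reference() -> Glut2Reference:
    """Construct the synthetic GLUT2 stand-in transcript (see Glut2Reference)."""
    codons = []
    codons.append("ATG")  # 1
    codons += ["GCT"] * 17  # 2-18
    codons.append("CCT")  # 19  (Pro; c.55C>T gives p.P19S)
    codons += ["GCT"] * 197  # 20-216
    # forward primer occupies c.649-668
    codons += ["CCT", "GGG", "CAA", "TCA", "CGA", "GCT"]  # 217-222
    codons.append("ATG")  # 223 (primer tail AT + G)
    codons += ["GCT"] * 33  # 224-256
    codons.append("GCT")  # 257
    codons.append("TTG")  # 258  Leu; c.772-774
    codons.append("AAA")  # 259  c.775-777
    codons.append("AGC")  # 260  c.778-780 (deleted octamer ends at 779)
    codons += ["GCA"] * 13  # 261-273; shifted frame reads CAG across these
    codons.append("CTG")  # 274; shifted frame meets TGA at c.821-823
    codons.append("ACC")  # 275
    codons += ["GCT"] * 57  # 276-332
    codons.append("GCG")  # 333; reverse-primer site starts at c.999
    codons += ["CAT", "TTT", "CCA", "GAC", "AGC", "TGG"]  # 334-339
    codons.append("ACT")  # 340 (primer tail A + CT)
    codons += ["GCT"] * 182  # 341-522
    codons.append("TAA")  # stop
    cds = "".join(codons)

    assert len(cds) == 1569
    assert cds[771:779] == "TTGAAAAG"  # c.772-779
    utr5 = "GGACGCAGAGCTCAGGTCCGAAGCAGGAAG"
    utr3 = "CAAGCCTGCCTTGTGTCTTCTCTTCCAAGA"
    return Glut2Reference(
        cds=cds,
        mrna=utr5 + cds + utr3,
        utr5=utr5,
        utr3=utr3,
        edit=parse_cdna_edit(GLUT2_EDIT_NOTATION),
        fwd_primer=GLUT2_FWD_PRIMER,
        rev_primer=GLUT2_REV_PRIMER,
    )
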
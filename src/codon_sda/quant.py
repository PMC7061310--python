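"""Isoacceptor quantification from multi-hit alignments.

Implements the two-pass filtering contract and the isoacceptor ambiguity
rules: reads with any hit on the tRNA-masked genome or on a pre-tRNA
flank are discarded (non-tRNA and unmature molecules respectively); of
the remaining reads, a read is counted for an anticodon if and only if
all of its best-tier hits (minimum edit distance) land on mature
clusters sharing that anticodon.  Reads whose best-tier hits span two or
more anticodons are discarded as ambiguous.  Reads ambiguous only among
isodecoders (same anticodon, different sequence) are therefore still
countable at isoacceptor level.

Abundances are reported as reads per million (RPM), with the assigned
read total as denominator so profiles sum to 1e6 and are comparable
across sequencing depths.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple

from .genetics import ANTICODON_TO_AA, STOP_COGNATE_ANTICODONS
from .reference import MEMBERSHIP_TSV, PRETRNA_FASTA, MASKED_FASTA, TRNACluster, PreTRNARecord

logger = logging.getLogger(__name__)


class ReadHit(NamedTuple):
    """One alignment of a read: half-open target interval + mismatch count."""

    target: str
    pos: int
    end: int
    nm: int


@dataclass
class ReadAlignmentSet:
    """All reported hits of one read."""

    read_id: str
    hits: list[ReadHit]
    seq: str = ""


class ReferenceIndex:
    """Classifies alignment targets as mature cluster / pre-tRNA / masked genome."""

    def __init__(
        self,
        clusters: Iterable[TRNACluster],
        pretrnas: Iterable[PreTRNARecord] = (),
        masked_chroms: Iterable[str] = (),
    ):
        self.cluster_anticodon = {c.cluster_id: c.anticodon for c in clusters}
        self.cluster_aa = {c.cluster_id: c.amino_acid for c in clusters}
        self.cluster_special = {c.cluster_id: c.is_special for c in clusters}
        #: pre-tRNA target name -> (gene body start, gene body end) within the record
        self.pretrna_body: dict[str, tuple[int, int]] = {
            f"pre_{p.gene_id}": p.gene_interval for p in pretrnas
        }
        self.masked_chroms = set(masked_chroms)

    @classmethod
    def from_refdir(cls, refdir) -> "ReferenceIndex":
        from Bio import SeqIO

        from .reference import read_mature_library

        refdir = Path(refdir)
        clusters = read_mature_library(refdir)
        pretrnas = []
        pre_path = refdir / PRETRNA_FASTA
        if pre_path.exists():
            for rec in SeqIO.parse(str(pre_path), "fasta"):
                name, left, right = rec.id.split("|")
                gene_id = name.removeprefix("pre_")
                pretrnas.append(
                    PreTRNARecord(
                        gene_id=gene_id,
                        seq=str(rec.seq),
                        flank_len=max(int(left), int(right)),
                        left_flank=int(left),
                        right_flank=int(right),
                    )
                )
        masked = []
        masked_path = refdir / MASKED_FASTA
        if masked_path.exists():
            masked = [rec.id for rec in SeqIO.parse(str(masked_path), "fasta")]
        return cls(clusters, pretrnas, masked)

    def classify(self, target: str) -> str:
        if target in self.cluster_anticodon:
            return "mature"
        if target in self.pretrna_body:
            return "pretrna"
        if target in self.masked_chroms:
            return "masked"
        raise ValueError(f"alignment target {target!r} not in the reference set")


@dataclass
class IsoacceptorProfile:
    """Per-sample anticodon-level abundance: counts and RPM views."""

    sample_id: str
    counts: dict[str, int] = field(default_factory=dict)
    total_assigned: int = 0
    discarded_ambiguous: int = 0
    discarded_premature: int = 0
    unmapped: int = 0

    @property
    def rpm(self) -> dict[str, float]:
        if self.total_assigned == 0:
            return {a: 0.0 for a in self.counts}
        return {a: c * 1e6 / self.total_assigned for a, c in self.counts.items()}

    def to_dataframe(self):
        import pandas as pd

        rpm = self.rpm
        sqrt_rpm = sqrt_normalize(self)
        raa = relative_anticodon_abundance(self)
        rows = []
        for a in sorted(self.counts):
            rows.append(
                {
                    "anticodon": a,
                    "amino_acid": ANTICODON_TO_AA.get(a, "NA"),
                    "count": self.counts[a],
                    "rpm": rpm[a],
                    "sqrt_rpm": sqrt_rpm[a],
                    "raa": raa.get(a, float("nan")),
                }
            )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# SAM parsing


def parse_sam(path) -> list[ReadAlignmentSet]:
    """Collect per-read hit sets from a SAM/BAM file (secondary hits included)."""
    import pysam

    reads: dict[str, ReadAlignmentSet] = {}
    with pysam.AlignmentFile(str(path), check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped:
                reads.setdefault(rec.query_name, ReadAlignmentSet(rec.query_name, []))
                continue
            nm = rec.get_tag("NM") if rec.has_tag("NM") else 0
            hit = ReadHit(
                target=rec.reference_name,
                pos=rec.reference_start,
                end=rec.reference_end,
                nm=int(nm),
            )
            rs = reads.setdefault(rec.query_name, ReadAlignmentSet(rec.query_name, []))
            rs.hits.append(hit)
            if rec.query_sequence and not rs.seq:
                rs.seq = rec.query_sequence
    return list(reads.values())


# ---------------------------------------------------------------------------
# filtering and assignment


def _overlaps_flank(hit: ReadHit, body: tuple[int, int]) -> bool:
    """True if the half-open hit interval touches either flank of a pre-tRNA."""
    body_start, body_end = body
    return hit.pos < body_start or hit.end > body_end


def filter_premature(
    reads: Iterable[ReadAlignmentSet], index: ReferenceIndex
) -> tuple[list[ReadAlignmentSet], int]:
    """Drop reads with any hit on a masked chromosome or a pre-tRNA flank."""
    retained: list[ReadAlignmentSet] = []
    discarded = 0
    for r in reads:
        drop = False
        for h in r.hits:
            kind = index.classify(h.target)
            if kind == "masked":
                drop = True
                break
            if kind == "pretrna" and _overlaps_flank(h, index.pretrna_body[h.target]):
                drop = True
                break
        if drop:
            discarded += 1
        else:
            retained.append(r)
    return retained, discarded


def assign_reads(
    reads: Iterable[ReadAlignmentSet],
    index: ReferenceIndex,
    sample_id: str = "sample",
) -> IsoacceptorProfile:
    """Count reads per anticodon under the best-tier unambiguity rule."""
    profile = IsoacceptorProfile(sample_id=sample_id)
    counts: dict[str, int] = {}
    for r in reads:
        mature_hits = [h for h in r.hits if index.classify(h.target) == "mature"]
        if not mature_hits:
            profile.unmapped += 1
            continue
        best_nm = min(h.nm for h in mature_hits)
        anticodons = {
            index.cluster_anticodon[h.target] for h in mature_hits if h.nm == best_nm
        }
        if len(anticodons) == 1:
            a = anticodons.pop()
            counts[a] = counts.get(a, 0) + 1
            profile.total_assigned += 1
        else:
            profile.discarded_ambiguous += 1
    profile.counts = counts
    return profile


def quantify(
    sam_path,
    index: ReferenceIndex,
    sample_id: str = "sample",
) -> IsoacceptorProfile:
    """Full per-sample quantification: parse, premature-filter, assign."""
    reads = parse_sam(sam_path)
    retained, n_premature = filter_premature(reads, index)
    profile = assign_reads(retained, index, sample_id=sample_id)
    profile.discarded_premature = n_premature
    return profile


# ---------------------------------------------------------------------------
# normalised views


def sqrt_normalize(profile: IsoacceptorProfile) -> dict[str, float]:
    """Element-wise square root of the RPM profile (order-preserving)."""
    return {a: math.sqrt(v) for a, v in profile.rpm.items()}


def relative_anticodon_abundance(profile: IsoacceptorProfile) -> dict[str, float]:
    """RAA: each anticodon's share of its amino-acid family's abundance.

    Families are defined by the cognate codon (reverse complement) under
    the standard genetic code; anticodons whose cognate codon is a stop
    are excluded with a warning.  All-zero families yield NaN entries.
    """
    rpm = profile.rpm
    fam_totals: dict[str, float] = {}
    for a, v in rpm.items():
        if a in STOP_COGNATE_ANTICODONS:
            logger.warning("anticodon %s decodes a stop codon; excluded from RAA", a)
            continue
        fam_totals[ANTICODON_TO_AA[a]] = fam_totals.get(ANTICODON_TO_AA[a], 0.0) + v
    raa: dict[str, float] = {}
    for a, v in rpm.items():
        if a in STOP_COGNATE_ANTICODONS:
            continue
        total = fam_totals[ANTICODON_TO_AA[a]]
        raa[a] = v / total if total > 0 else float("nan")
    return raa
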
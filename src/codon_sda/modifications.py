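"""Misincorporation-based tRNA modification site detection.

Many tRNA base modifications (m1A, m3C, m1G, ...) interfere with reverse
transcription and leave a mismatch footprint in sequencing reads.  This
module tallies per-position base calls over each mature tRNA cluster
using only reads that map uniquely at the gene level (to separate
misincorporation from mapping artefacts), calls candidate sites with a
transparent depth/alternative-fraction threshold, and projects site
positions onto a canonical 76-nt tRNA scaffold with Sprinzl-style
numbering so that sites on tRNAs with variable D-loops and V-regions are
comparable (e.g. the wobble position is "34" on every tRNA).

Sequencing cannot identify the chemical nature of a modification; the
output is a catalogue of candidate misincorporation positions.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Mapping

from Bio import Align

# ---------------------------------------------------------------------------
# canonical scaffold with Sprinzl-style numbering (76 nt, anticodon at 34-36)

TEMPLATE_SEQ = (
    "GCGGATTTAGCTCAGTTGGGAGAGCGCCAGACTGAAGATCTGGAGGTCCTGTGTTCGATCCACAGAATTCGCACCA"
)

ANTICODON_SLICE = slice(33, 36)  # 0-based offsets of positions 34-36

_REGIONS = [
    (1, 7, "acceptor-stem"),
    (8, 9, "linker"),
    (10, 13, "D-stem"),
    (14, 21, "D-loop"),
    (22, 25, "D-stem"),
    (26, 26, "core"),
    (27, 31, "anticodon-stem"),
    (32, 38, "anticodon-loop"),
    (39, 43, "anticodon-stem"),
    (44, 48, "V-region"),
    (49, 53, "T-stem"),
    (54, 60, "T-loop"),
    (61, 65, "T-stem"),
    (66, 72, "acceptor-stem"),
    (73, 73, "discriminator"),
    (74, 76, "CCA"),
]


def region_of(position: int) -> str:
    """Structural region of a 1-based scaffold position."""
    for lo, hi, name in _REGIONS:
        if lo <= position <= hi:
            return name
    raise ValueError(f"position {position} outside the 76-nt scaffold")


# ---------------------------------------------------------------------------
# pileup


@dataclass
class PileupColumn:
    """Base tally at one mature-sequence position of one cluster."""

    cluster_id: str
    position: int
    ref_base: str
    depth: int
    base_counts: dict[str, int]


@dataclass
class ModificationSite:
    """A candidate misincorporation site with its scaffold coordinate."""

    cluster_id: str
    position: int
    ref_base: str
    dominant_alt: str
    alt_fraction: float
    depth: int
    model_position: str = ""


def pileup(sam_path, library: Mapping[str, str], index=None) -> list[PileupColumn]:
    """Per-position base tallies from gene-level uniquely mapped reads.

    A read is admitted iff exactly one of its best-tier (minimum edit
    distance) hits lands on a mature cluster.  ``library`` maps cluster
    ids to mature sequences.  With a :class:`~codon_sda.quant.ReferenceIndex`
    as ``index``, reads touching masked chromosomes or pre-tRNA flanks
    are filtered first and other non-cluster targets ignored; without
    one, a read referencing an unknown cluster is an error.
    """
    import pysam

    with pysam.AlignmentFile(str(sam_path), check_sq=False) as sam:
        records = []
        for rec in sam:
            if rec.is_unmapped:
                continue
            nm = int(rec.get_tag("NM")) if rec.has_tag("NM") else 0
            records.append(
                (
                    rec.query_name,
                    rec.reference_name,
                    nm,
                    rec.reference_start,
                    rec.query_sequence,
                    rec.cigartuples,
                )
            )
    if index is not None:
        from .quant import ReadAlignmentSet, ReadHit, filter_premature

        by_read: dict[str, ReadAlignmentSet] = {}
        for qname, target, nm, pos, seq, cigar in records:
            ref_len = sum(n for op, n in (cigar or []) if op in (0, 2, 3, 7, 8))
            rs = by_read.setdefault(qname, ReadAlignmentSet(qname, []))
            rs.hits.append(ReadHit(target, pos, pos + ref_len, nm))
        retained, _ = filter_premature(by_read.values(), index)
        keep = {r.read_id for r in retained}
        records = [r for r in records if r[0] in keep and r[1] in library]

    best: dict[str, list] = {}
    for qname, target, nm, *_ in records:
        best.setdefault(qname, []).append((nm, target))
    unique_reads = set()
    for qname, hits in best.items():
        best_nm = min(nm for nm, _ in hits)
        tier = [t for nm, t in hits if nm == best_nm]
        if len(tier) == 1:
            unique_reads.add((qname, tier[0]))

    counts: dict[str, list[dict[str, int]]] = {}
    for qname, target, nm, pos, seq, cigar in records:
        if (qname, target) not in unique_reads or seq is None:
            continue
        if target not in library:
            raise ValueError(f"read {qname} references unknown cluster {target!r}")
        ref_seq = library[target]
        cols = counts.setdefault(
            target, [{b: 0 for b in "ACGT"} | {"del": 0} for _ in ref_seq]
        )
        qpos, rpos = 0, pos
        for op, length in cigar or [(0, len(seq))]:
            if op in (0, 7, 8):  # M, =, X
                for k in range(length):
                    cols[rpos + k][seq[qpos + k]] += 1
                qpos += length
                rpos += length
            elif op == 1 or op == 4:  # I, S consume query only
                qpos += length
            elif op == 2:  # D consumes reference
                for k in range(length):
                    cols[rpos + k]["del"] += 1
                rpos += length
            elif op == 3:  # N
                rpos += length

    out: list[PileupColumn] = []
    for cluster_id in sorted(counts):
        ref_seq = library[cluster_id]
        for i, tally in enumerate(counts[cluster_id]):
            depth = sum(tally.values())
            if depth == 0:
                continue
            out.append(
                PileupColumn(
                    cluster_id=cluster_id,
                    position=i,
                    ref_base=ref_seq[i],
                    depth=depth,
                    base_counts=dict(tally),
                )
            )
    return out


def call_sites(
    columns: Iterable[PileupColumn],
    min_depth: int = 20,
    min_fraction: float = 0.1,
) -> list[ModificationSite]:
    """Threshold caller: emit sites with depth >= min_depth and
    non-reference fraction >= min_fraction, ordered by (cluster, position)."""
    if min_depth < 1 or not (0 < min_fraction <= 1):
        raise ValueError("min_depth >= 1 and 0 < min_fraction <= 1 required")
    sites: list[ModificationSite] = []
    for col in sorted(columns, key=lambda c: (c.cluster_id, c.position)):
        if col.depth < min_depth:
            continue
        ref_count = col.base_counts.get(col.ref_base, 0)
        alt = col.depth - ref_count
        frac = alt / col.depth
        if frac < min_fraction or alt == 0:
            continue
        alts = {b: n for b, n in col.base_counts.items() if b != col.ref_base and n > 0}
        dominant = max(sorted(alts), key=lambda b: alts[b])
        sites.append(
            ModificationSite(
                cluster_id=col.cluster_id,
                position=col.position,
                ref_base=col.ref_base,
                dominant_alt=dominant,
                alt_fraction=frac,
                depth=col.depth,
            )
        )
    return sites


# ---------------------------------------------------------------------------
# projection onto the scaffold


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = -3.0
    aligner.open_gap_score = -3.0
    aligner.extend_gap_score = -1.0
    return aligner


@lru_cache(maxsize=1024)
def _align_to_template(cluster_seq: str) -> tuple[float, tuple]:
    """Global alignment of a mature sequence to the scaffold.

    Returns (chance-corrected identity, aligned block pairs); the first
    reported traceback is used (deterministic, leftmost-biased).  Raw
    identity (matches over alignment columns) is rescaled by the 25%
    agreement expected between unrelated DNA sequences, so unrelated
    input scores near zero rather than near one half.
    """
    aln = _make_aligner().align(TEMPLATE_SEQ, cluster_seq)[0]
    matches = 0
    for (ts, te), (qs, qe) in zip(*aln.aligned):
        for k in range(te - ts):
            if TEMPLATE_SEQ[ts + k] == cluster_seq[qs + k]:
                matches += 1
    raw = matches / aln.length
    identity = max(0.0, (raw - 0.25) / 0.75)
    blocks = tuple((ts, te, qs, qe) for (ts, te), (qs, qe) in zip(*aln.aligned))
    return identity, blocks


def map_to_model(
    position: int, cluster_seq: str, min_identity: float = 0.4
) -> str:
    """Project a mature-sequence offset to a scaffold coordinate label.

    Aligned positions get the Sprinzl-style number ("34"); positions in
    insertions relative to the scaffold get the region name of the last
    aligned scaffold column ("V-region"); sequences below the identity
    floor return "unmapped".
    """
    identity, blocks = _align_to_template(cluster_seq.upper())
    if identity < min_identity:
        return "unmapped"
    last_t_end = 0
    for ts, te, qs, qe in blocks:
        if qs <= position < qe:
            return str(ts + (position - qs) + 1)
        if qe <= position:
            last_t_end = te
    anchor = last_t_end if last_t_end > 0 else blocks[0][0] + 1
    return region_of(min(anchor, len(TEMPLATE_SEQ)))


def annotate_sites(
    sites: Iterable[ModificationSite],
    library: Mapping[str, str],
    min_identity: float = 0.4,
) -> list[ModificationSite]:
    """Fill ``model_position`` for every site via scaffold projection."""
    out = []
    for s in sites:
        s.model_position = map_to_model(s.position, library[s.cluster_id], min_identity)
        out.append(s)
    return out
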
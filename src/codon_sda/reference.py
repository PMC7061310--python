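"""Mature tRNA reference construction.

Parses tRNA gene annotations (tRNAscan-SE tabular output or BED12), builds
the mature tRNA library (introns spliced out, a single 3' CCA appended,
100%-identical sequences collapsed into clusters), and emits the artifacts
for two-pass read filtering: pre-tRNA records (gene plus genomic flanks)
and a genome with every tRNA locus hard-masked to N.

Coordinates are 0-based half-open internally; both input dialects are
normalised at parse time.  Minus-strand genes carry gene-oriented
(reverse-complemented) sequences, and intron offsets are gene-local and
gene-oriented.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from .genetics import (
    SPECIAL_AA_LABELS,
    THREE_TO_ONE,
    is_valid_anticodon,
    revcomp,
)

logger = logging.getLogger(__name__)

MITO_CHROM_NAMES = {"chrM", "chrMT", "MT", "M", "mito"}


@dataclass
class TRNAGene:
    """One annotated tRNA gene, gene-oriented.

    ``introns`` are (start, end) offsets local to the gene and in gene
    orientation (0-based half-open).  ``genomic_seq`` is the gene-oriented
    nucleotide sequence of the full locus (introns included).
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    amino_acid: str
    anticodon: str
    introns: list[tuple[int, int]] = field(default_factory=list)
    genomic_seq: str = ""
    is_mito: bool = False

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"gene {self.gene_id}: end ({self.end}) must exceed start ({self.start})"
            )
        if len(self.anticodon) != 3:
            raise ValueError(f"gene {self.gene_id}: anticodon must be a 3-mer")
        if self.strand not in "+-":
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        length = self.end - self.start
        if self.genomic_seq and len(self.genomic_seq) != length:
            raise ValueError(
                f"gene {self.gene_id}: sequence length {len(self.genomic_seq)} "
                f"!= span {length}"
            )
        prev_end = -1
        for s, e in self.introns:
            if not (0 <= s < e <= length):
                raise ValueError(f"gene {self.gene_id}: intron ({s},{e}) outside gene span")
            if s < prev_end:
                raise ValueError(f"gene {self.gene_id}: overlapping introns")
            prev_end = e

    @property
    def is_special(self) -> bool:
        """Mitochondrial or non-standard (SeC/Sup/Und/iMet) gene."""
        return self.is_mito or self.amino_acid in SPECIAL_AA_LABELS

    def mature_seq(self) -> str:
        """Spliced gene sequence with one 3' CCA appended."""
        seq = self.genomic_seq
        for s, e in sorted(self.introns, reverse=True):
            seq = seq[:s] + seq[e:]
        if not seq:
            raise ValueError(f"gene {self.gene_id}: intron removal emptied the sequence")
        if seq.endswith("CCA"):
            logger.info("gene %s already ends in CCA; appending one more", self.gene_id)
        return seq + "CCA"


@dataclass
class TRNACluster:
    """A set of tRNA genes with byte-identical mature sequence."""

    cluster_id: str
    mature_seq: str
    member_gene_ids: list[str]
    anticodon: str
    amino_acid: str
    is_special: bool = False

    def __post_init__(self) -> None:
        if not self.mature_seq.endswith("CCA"):
            raise ValueError(f"cluster {self.cluster_id}: mature sequence must end in CCA")
        if not self.member_gene_ids:
            raise ValueError(f"cluster {self.cluster_id}: no member genes")


@dataclass
class PreTRNARecord:
    """Unspliced gene with genomic flanks (gene-oriented).

    ``left_flank``/``right_flank`` are the flank lengths actually present
    after clipping at chromosome edges, in gene orientation (left = 5').
    """

    gene_id: str
    seq: str
    flank_len: int
    left_flank: int
    right_flank: int
    clipped: bool = False

    @property
    def gene_interval(self) -> tuple[int, int]:
        """Half-open interval of the gene body within ``seq``."""
        return self.left_flank, len(self.seq) - self.right_flank


# ---------------------------------------------------------------------------
# annotation parsing


def _load_genome(genome) -> dict[str, str]:
    """Accept a dict of sequences or a FASTA path."""
    if isinstance(genome, dict):
        return {k: v.upper() for k, v in genome.items()}
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(genome), "fasta")}


def _looks_like_bed(lines: list[str]) -> bool:
    for ln in lines:
        if not ln.strip() or ln.startswith(("#", "track", "browser")):
            continue
        fields = ln.rstrip("\n").split("\t")
        if len(fields) >= 12 and fields[5] in "+-":
            try:
                int(fields[1]), int(fields[2])
                return True
            except ValueError:
                return False
        return False
    return False


def _normalize_aa(label: str) -> str:
    if label in SPECIAL_AA_LABELS:
        return label
    if label in THREE_TO_ONE:
        return label
    return label


def parse_trna_annotation(annotation_file, genome, dialect: str = "auto") -> list[TRNAGene]:
    """Parse a tRNA gene annotation into gene-oriented :class:`TRNAGene` records.

    Parameters
    ----------
    annotation_file
        Path to tRNAscan-SE tabular output (1-based inclusive coordinates,
        start > end on the minus strand) or BED12 (blocks are exons).
    genome
        FASTA path or dict of chromosome sequences.
    dialect
        ``"trnascan"``, ``"bed"`` or ``"auto"``.

    Rows whose anticodon contains non-ACGT characters are rejected with a
    warning; coordinates outside the chromosome raise a ``ValueError``
    naming the offending row.
    """
    chroms = _load_genome(genome)
    lines = Path(annotation_file).read_text().splitlines()
    if dialect == "auto":
        dialect = "bed" if _looks_like_bed(lines) else "trnascan"
    if dialect == "bed":
        return _parse_bed(lines, chroms)
    return _parse_trnascan(lines, chroms)


def _gene_from_genomic(
    gene_id: str,
    chrom: str,
    start: int,
    end: int,
    strand: str,
    aa: str,
    anticodon: str,
    genomic_introns: list[tuple[int, int]],
    chroms: dict[str, str],
) -> TRNAGene:
    if chrom not in chroms:
        raise ValueError(f"row {gene_id}: chromosome {chrom!r} not in genome")
    chrom_len = len(chroms[chrom])
    if start < 0 or end > chrom_len:
        raise ValueError(
            f"row {gene_id}: coordinates {start}-{end} outside chromosome "
            f"{chrom} (length {chrom_len})"
        )
    plus_seq = chroms[chrom][start:end]
    if strand == "+":
        seq = plus_seq
        introns = [(s - start, e - start) for s, e in genomic_introns]
    else:
        seq = revcomp(plus_seq)
        introns = [(end - e, end - s) for s, e in genomic_introns]
    introns.sort()
    return TRNAGene(
        gene_id=gene_id,
        chrom=chrom,
        start=start,
        end=end,
        strand=strand,
        amino_acid=aa,
        anticodon=anticodon,
        introns=introns,
        genomic_seq=seq,
        is_mito=chrom in MITO_CHROM_NAMES,
    )


def _parse_trnascan(lines: list[str], chroms: dict[str, str]) -> list[TRNAGene]:
    genes: list[TRNAGene] = []
    for ln in lines:
        if not ln.strip():
            continue
        fields = ln.rstrip("\n").split("\t")
        fields = [f.strip() for f in fields]
        # skip the three header lines of standard tRNAscan-SE output
        if not fields[0] or fields[0].startswith(("Sequence", "Name", "---", "#")):
            continue
        try:
            begin, stop = int(fields[2]), int(fields[3])
        except (ValueError, IndexError):
            continue
        chrom, num = fields[0], fields[1]
        aa = _normalize_aa(fields[4])
        anticodon = fields[5].upper()
        gene_id = f"{chrom}.trna{num}-{aa}{anticodon}"
        if not is_valid_anticodon(anticodon):
            logger.warning("row %s: unknown anticodon %r, rejected", gene_id, anticodon)
            continue
        if begin <= stop:
            strand, start, end = "+", begin - 1, stop
        else:
            strand, start, end = "-", stop - 1, begin
        genomic_introns: list[tuple[int, int]] = []
        if len(fields) >= 8:
            try:
                ib, ie = int(fields[6]), int(fields[7])
            except ValueError:
                ib = ie = 0
            if ib and ie:
                lo, hi = min(ib, ie), max(ib, ie)
                genomic_introns.append((lo - 1, hi))
        genes.append(
            _gene_from_genomic(
                gene_id, chrom, start, end, strand, aa, anticodon, genomic_introns, chroms
            )
        )
    return genes


def _parse_bed(lines: list[str], chroms: dict[str, str]) -> list[TRNAGene]:
    genes: list[TRNAGene] = []
    for idx, ln in enumerate(lines):
        if not ln.strip() or ln.startswith(("#", "track", "browser")):
            continue
        f = ln.rstrip("\n").split("\t")
        chrom, start, end, name = f[0], int(f[1]), int(f[2]), f[3]
        strand = f[5]
        # gtRNAdb-style name: tRNA-Pro-AGG-1-1
        parts = name.split("-")
        if len(parts) >= 3 and parts[0] in ("tRNA", "trna"):
            aa, anticodon = _normalize_aa(parts[1]), parts[2].upper()
        else:
            raise ValueError(f"row {idx + 1}: cannot parse amino acid/anticodon from {name!r}")
        if not is_valid_anticodon(anticodon):
            logger.warning("row %s: unknown anticodon %r, rejected", name, anticodon)
            continue
        genomic_introns: list[tuple[int, int]] = []
        if len(f) >= 12 and int(f[9]) > 1:
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            starts = [int(x) for x in f[11].rstrip(",").split(",")]
            for i in range(len(sizes) - 1):
                intron_start = start + starts[i] + sizes[i]
                intron_end = start + starts[i + 1]
                genomic_introns.append((intron_start, intron_end))
        genes.append(
            _gene_from_genomic(
                name, chrom, start, end, strand, aa, anticodon, genomic_introns, chroms
            )
        )
    return genes


# ---------------------------------------------------------------------------
# mature library


def build_mature_library(genes: list[TRNAGene]) -> list[TRNACluster]:
    """Collapse genes into clusters of 100%-identical mature sequences.

    Every gene is clustered (so that reads can be assigned to it);
    mitochondrial and SeC/Sup/Und/iMet clusters are flagged ``is_special``
    and excluded by downstream metric-facing code by default.
    """
    if not genes:
        raise ValueError("empty gene list")
    by_seq: dict[tuple[str, str, str], list[TRNAGene]] = {}
    for g in genes:
        key = (g.mature_seq(), g.anticodon, g.amino_acid)
        by_seq.setdefault(key, []).append(g)

    counters: dict[tuple[str, str], int] = {}
    clusters: list[TRNACluster] = []
    for (seq, anticodon, aa), members in sorted(
        by_seq.items(),
        key=lambda kv: (kv[0][2], kv[0][1], min(g.gene_id for g in kv[1])),
    ):
        n = counters.get((aa, anticodon), 0) + 1
        counters[(aa, anticodon)] = n
        clusters.append(
            TRNACluster(
                cluster_id=f"{aa}-{anticodon}-{n}",
                mature_seq=seq,
                member_gene_ids=sorted(g.gene_id for g in members),
                anticodon=anticodon,
                amino_acid=aa,
                is_special=any(g.is_special for g in members),
            )
        )
    return clusters


def build_pretrna_and_mask(
    genes: list[TRNAGene], genome, flank_len: int = 50
) -> tuple[list[PreTRNARecord], dict[str, str]]:
    """Pre-tRNA records (gene + genomic flanks) and an N-masked genome.

    Flanks come from the unmasked genome and are clipped at chromosome
    edges (clips are flagged and logged).  Records are gene-oriented.
    """
    if flank_len < 0:
        raise ValueError("flank_len must be >= 0")
    chroms = _load_genome(genome)
    masked = {name: bytearray(seq, "ascii") for name, seq in chroms.items()}
    records: list[PreTRNARecord] = []
    for g in genes:
        seq = chroms[g.chrom]
        lo = max(0, g.start - flank_len)
        hi = min(len(seq), g.end + flank_len)
        clipped = (lo != g.start - flank_len) or (hi != g.end + flank_len)
        if clipped:
            logger.info("pre-tRNA %s: flank clipped at chromosome edge", g.gene_id)
        plus = seq[lo:hi]
        left_plus = g.start - lo
        right_plus = hi - g.end
        if g.strand == "+":
            pre_seq, left, right = plus, left_plus, right_plus
        else:
            pre_seq, left, right = revcomp(plus), right_plus, left_plus
        records.append(
            PreTRNARecord(
                gene_id=g.gene_id,
                seq=pre_seq,
                flank_len=flank_len,
                left_flank=left,
                right_flank=right,
                clipped=clipped,
            )
        )
        masked[g.chrom][g.start : g.end] = b"N" * (g.end - g.start)
    return records, {name: buf.decode("ascii") for name, buf in masked.items()}


# ---------------------------------------------------------------------------
# reference directory I/O

MATURE_FASTA = "mature.fa"
PRETRNA_FASTA = "pretrna.fa"
MASKED_FASTA = "masked_genome.fa"
MEMBERSHIP_TSV = "clusters.tsv"


def _write_fasta(path: Path, records: list[tuple[str, str]], width: int = 70) -> None:
    with open(path, "w") as fh:
        for header, seq in records:
            fh.write(f">{header}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_reference(
    outdir,
    clusters: list[TRNACluster],
    pretrnas: list[PreTRNARecord] | None = None,
    masked_genome: dict[str, str] | None = None,
) -> None:
    """Write the mature library, membership table, pre-tRNAs, masked genome."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _write_fasta(
        outdir / MATURE_FASTA,
        [
            (
                f"{c.cluster_id}|{c.anticodon}|{c.amino_acid}|{len(c.member_gene_ids)}",
                c.mature_seq,
            )
            for c in clusters
        ],
    )
    with open(outdir / MEMBERSHIP_TSV, "w") as fh:
        fh.write("cluster_id\tanticodon\tamino_acid\tis_special\tgene_id\n")
        for c in clusters:
            for gid in c.member_gene_ids:
                fh.write(
                    f"{c.cluster_id}\t{c.anticodon}\t{c.amino_acid}\t"
                    f"{int(c.is_special)}\t{gid}\n"
                )
    if pretrnas is not None:
        _write_fasta(
            outdir / PRETRNA_FASTA,
            [
                (f"pre_{p.gene_id}|{p.left_flank}|{p.right_flank}", p.seq)
                for p in pretrnas
            ],
        )
    if masked_genome is not None:
        _write_fasta(outdir / MASKED_FASTA, sorted(masked_genome.items()))


def read_mature_library(refdir) -> list[TRNACluster]:
    """Re-read the mature library written by :func:`write_reference`."""
    from Bio import SeqIO

    refdir = Path(refdir)
    members: dict[str, list[str]] = {}
    special: dict[str, bool] = {}
    with open(refdir / MEMBERSHIP_TSV) as fh:
        next(fh)
        for ln in fh:
            cid, _ac, _aa, is_special, gid = ln.rstrip("\n").split("\t")
            members.setdefault(cid, []).append(gid)
            special[cid] = bool(int(is_special))
    clusters = []
    for rec in SeqIO.parse(str(refdir / MATURE_FASTA), "fasta"):
        cid, anticodon, aa, _n = rec.id.split("|")
        clusters.append(
            TRNACluster(
                cluster_id=cid,
                mature_seq=str(rec.seq).upper(),
                member_gene_ids=sorted(members[cid]),
                anticodon=anticodon,
                amino_acid=aa,
                is_special=special[cid],
            )
        )
    return clusters
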
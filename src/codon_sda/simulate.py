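"""Deterministic synthetic data with known ground truth.

Generates every input the toolkit consumes, at desk scale: a toy genome
with intron-bearing and duplicated tRNA genes built from the canonical
76-nt scaffold (so the structural mapper works on fixtures), small-RNA
reads drawn from known isoacceptor abundances with planted
misincorporation sites and optional unmature/background contamination,
random coding sequences and expression profiles, and cohort tables
(methylation/copy-number regressions, group-shifted SDAw matrices,
exponential survival with a declared hazard ratio).

All sampling is driven by one ``numpy`` Generator seeded from the
config; identical config + seed reproduces byte-identical outputs.
Synthetic tRNA genes are scaffold variants (anticodon substitution plus
isodecoder point substitutions), which emulates isodecoder ambiguity but
not real human tRNA sequence diversity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genetics import AA_THREE_LETTER, ANTICODON_TO_AA, ALL_ANTICODONS, SENSE_CODONS, revcomp
from .metrics import SDA_CODONS
from .modifications import TEMPLATE_SEQ
from .quant import ReadAlignmentSet, ReadHit
from .reference import PreTRNARecord, TRNACluster, TRNAGene

#: anticodons of the default toy panel (several multi-member families)
DEFAULT_PANEL = (
    "AGG", "TGG", "CGG", "GGG",   # Pro
    "AGC", "TGC", "CGC",          # Ala
    "GCC", "TCC", "CCC",          # Gly
    "AAT", "GAT", "TAT",          # Ile
    "GAA",                        # Phe
    "TTT", "CTT",                 # Lys
    "GTA",                        # Tyr
    "GCA",                        # Cys
    "CCA",                        # Trp
    "CAT",                        # Met
)

#: scaffold offsets safe for isodecoder point substitutions (V-region, D-loop)
_VARIANT_OFFSETS = (44, 46, 16, 20)

_INTRON_SEQ = "GTAAGTATCAG"  # 11 nt, inserted after scaffold position 37


@dataclass
class SimulationConfig:
    """Study conditions for all generators.

    The cohort block mirrors the scale of the analyses the toolkit is
    built for: 22 conditions x 64 isoacceptors (1,408 regressions),
    two-group comparisons of 50 vs 50 samples, and survival cohorts of
    200 patients split into bottom/top 40% groups.
    """

    seed: int = 0
    # reference
    anticodon_panel: tuple[str, ...] = DEFAULT_PANEL
    n_clusters_per_anticodon: int = 2
    intron_prob: float = 0.2
    # reads
    read_depth: int = 20_000
    read_len: tuple[int, int] = (25, 45)
    error_rate: float = 0.001
    planted_modifications: list[tuple[str, int, float]] = field(default_factory=list)
    premature_fraction: float = 0.0
    background_fraction: float = 0.0
    # expression / CDS
    n_cds: int = 200
    cds_len_codons: tuple[int, int] = (100, 300)
    expression_mu: float = 2.0
    expression_sigma: float = 1.0
    # cohort
    n_conditions: int = 22
    n_isoacceptors: int = 64
    n_per_group: int = 50
    regression_truth: tuple[float, float, float, float] = (2.0, -3.0, 1.5, 0.1)
    sdaw_shift: float = 2.0
    shifted_codons: tuple[str, ...] = ("CCA", "GCG")
    # survival
    n_patients: int = 200
    hazard_ratio: float = 3.0
    baseline_hazard: float = 0.05
    censoring_rate: float = 0.3
    survival_fraction: float = 0.4


# ---------------------------------------------------------------------------
# reference


def _toy_mature_body(anticodon: str, variant_index: int) -> str:
    """Scaffold gene body (73 nt, no CCA) with the anticodon substituted
    and, for variant_index > 0, one isodecoder point substitution."""
    body = list(TEMPLATE_SEQ[:-3])
    body[33:36] = list(anticodon)
    if variant_index > 0:
        off = _VARIANT_OFFSETS[(variant_index - 1) % len(_VARIANT_OFFSETS)]
        cycle = {"A": "C", "C": "G", "G": "T", "T": "A"}
        for _ in range(1 + (variant_index - 1) // len(_VARIANT_OFFSETS)):
            body[off] = cycle[body[off]]
    return "".join(body)


def simulate_reference(config: SimulationConfig):
    """Toy genome + tRNAscan-style annotation with known gene structures.

    Guarantees at least one identical-mature-sequence duplicate pair
    (the duplicate carries an intron, so the genomic sequences differ)
    and, at intron_prob = 1, an intron in every gene.  Returns
    (genome dict, annotation text, gene truth table).
    """
    rng = np.random.default_rng(config.seed)
    spacer = lambda n: "".join(rng.choice(list("ACGT"), size=n))

    jobs: list[tuple[str, int, bool]] = []  # (anticodon, variant index, force intron)
    for a in config.anticodon_panel:
        if a not in ANTICODON_TO_AA:
            raise ValueError(f"anticodon {a} decodes a stop codon; infeasible panel")
        for j in range(config.n_clusters_per_anticodon):
            jobs.append((a, j, bool(rng.random() < config.intron_prob)))
    # duplicate of the first gene, intron-bearing: same mature sequence
    jobs.append((config.anticodon_panel[0], 0, True))

    chrom_parts = [spacer(100)]
    pos = 100
    rows = []
    truth_rows = []
    for i, (anticodon, variant, with_intron) in enumerate(jobs):
        body = _toy_mature_body(anticodon, variant)
        if with_intron:
            genomic = body[:37] + _INTRON_SEQ + body[37:]
            intron_local = (37, 37 + len(_INTRON_SEQ))
        else:
            genomic = body
            intron_local = None
        strand = "+" if i % 3 else "-"
        plus_seq = genomic if strand == "+" else revcomp(genomic)
        start = pos
        end = pos + len(plus_seq)
        chrom_parts.append(plus_seq)
        chrom_parts.append(spacer(120))
        pos = end + 120

        aa = AA_THREE_LETTER[ANTICODON_TO_AA[anticodon]]
        if strand == "+":
            begin_1, end_1 = start + 1, end
            if intron_local:
                ib = start + intron_local[0] + 1
                ie = start + intron_local[1]
            else:
                ib = ie = 0
        else:
            begin_1, end_1 = end, start + 1
            if intron_local:
                # gene-local (s, e) on minus strand sits at genomic
                # [end - e, end - s); report 1-based inclusive
                ib = end - intron_local[1] + 1
                ie = end - intron_local[0]
            else:
                ib = ie = 0
        rows.append(
            f"chr1\t{i + 1}\t{begin_1}\t{end_1}\t{aa}\t{anticodon}\t{ib}\t{ie}\t60.0"
        )
        truth_rows.append(
            {
                "row": i + 1,
                "anticodon": anticodon,
                "variant": variant,
                "strand": strand,
                "intron": bool(with_intron),
                "mature_seq": body + "CCA",
            }
        )
    genome = {"chr1": "".join(chrom_parts)}
    annotation = "\n".join(rows) + "\n"
    return genome, annotation, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# reads


def _true_cluster_probs(
    rng: np.random.Generator, clusters: list[TRNACluster]
) -> pd.Series:
    """Log-normal cluster abundances normalised to 1."""
    raw = rng.lognormal(mean=0.0, sigma=1.0, size=len(clusters))
    probs = raw / raw.sum()
    return pd.Series(probs, index=[c.cluster_id for c in clusters])


def simulate_reads(
    config: SimulationConfig,
    clusters: list[TRNACluster],
    true_abundances: pd.Series | None = None,
    pretrnas: list[PreTRNARecord] | None = None,
    masked_chrom_len: int = 0,
):
    """Reads + multi-hit alignment records from known cluster abundances.

    Alignments follow an exact-substring model: every exact occurrence of
    the read in any mature cluster is a zero-mismatch hit; reads altered
    by sequencing error or a planted misincorporation that match nowhere
    exactly get a single hit at their true origin with NM = the mismatch
    count.  ``premature_fraction`` of reads are drawn across a pre-tRNA
    flank boundary and ``background_fraction`` from the masked genome, to
    exercise the first-pass filter.  Returns (alignment sets, truth table).
    """
    rng = np.random.default_rng(config.seed + 1)
    seqs = {c.cluster_id: c.mature_seq for c in clusters}
    if true_abundances is None:
        true_abundances = _true_cluster_probs(rng, clusters)
    probs = true_abundances / true_abundances.sum()
    anticodon_of = {c.cluster_id: c.anticodon for c in clusters}

    # planted modification sites: cluster -> (offset, alt base, fraction)
    cycle = {"A": "G", "C": "T", "G": "A", "T": "C"}
    planted: dict[str, list[tuple[int, str, float]]] = {}
    for anticodon, model_pos, fraction in config.planted_modifications:
        for c in clusters:
            if c.anticodon == anticodon:
                off = model_pos - 1
                planted.setdefault(c.cluster_id, []).append(
                    (off, cycle[c.mature_seq[off]], fraction)
                )

    n_pre = int(round(config.read_depth * config.premature_fraction))
    n_bg = int(round(config.read_depth * config.background_fraction))
    n_mature = config.read_depth - n_pre - n_bg

    choices = rng.choice(probs.index.to_numpy(), size=n_mature, p=probs.to_numpy())
    read_sets: list[ReadAlignmentSet] = []
    truth_rows = []
    lo, hi = config.read_len

    for i, cluster_id in enumerate(choices):
        ref = seqs[cluster_id]
        length = min(int(rng.integers(lo, hi + 1)), len(ref))
        start = int(rng.integers(0, len(ref) - length + 1))
        read = list(ref[start : start + length])
        for off, alt, fraction in planted.get(cluster_id, []):
            if start <= off < start + length and rng.random() < fraction:
                read[off - start] = alt
        if config.error_rate > 0:
            err_mask = rng.random(length) < config.error_rate
            for k in np.flatnonzero(err_mask):
                read[k] = cycle[read[k]]
        read_str = "".join(read)

        hits = []
        for cid, s in seqs.items():
            at = s.find(read_str)
            while at != -1:
                hits.append(ReadHit(cid, at, at + length, 0))
                at = s.find(read_str, at + 1)
        if not hits:
            nm = sum(a != b for a, b in zip(read_str, ref[start : start + length]))
            hits = [ReadHit(cluster_id, start, start + length, nm)]
        rid = f"read{i}"
        read_sets.append(ReadAlignmentSet(read_id=rid, hits=hits, seq=read_str))
        truth_rows.append(
            {"read_id": rid, "origin": cluster_id, "anticodon": anticodon_of[cluster_id]}
        )

    if pretrnas:
        for i in range(n_pre):
            p = pretrnas[int(rng.integers(0, len(pretrnas)))]
            body_start, _ = p.gene_interval
            length = min(int(rng.integers(lo, hi + 1)), len(p.seq))
            # straddle the 5' flank boundary by at least 1 nt
            left = max(0, body_start - max(1, length // 2))
            start = min(left, len(p.seq) - length)
            rid = f"pre{i}"
            read_sets.append(
                ReadAlignmentSet(
                    read_id=rid,
                    hits=[ReadHit(f"pre_{p.gene_id}", start, start + length, 0)],
                    seq=p.seq[start : start + length],
                )
            )
            truth_rows.append({"read_id": rid, "origin": "premature", "anticodon": ""})
    if masked_chrom_len and n_bg:
        for i in range(n_bg):
            length = int(rng.integers(lo, hi + 1))
            start = int(rng.integers(0, max(1, masked_chrom_len - length)))
            rid = f"bg{i}"
            read_sets.append(
                ReadAlignmentSet(
                    read_id=rid,
                    hits=[ReadHit("chr1", start, start + length, 0)],
                    seq="",
                )
            )
            truth_rows.append({"read_id": rid, "origin": "background", "anticodon": ""})
    return read_sets, pd.DataFrame(truth_rows)


def write_sam(path, read_sets: list[ReadAlignmentSet], target_lengths: dict[str, int]):
    """Write multi-hit alignment sets as a SAM file (secondaries flagged)."""
    import pysam

    names = sorted(target_lengths)
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": n, "LN": int(target_lengths[n])} for n in names],
    }
    tid = {n: i for i, n in enumerate(names)}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for rs in read_sets:
            for j, hit in enumerate(rs.hits):
                a = pysam.AlignedSegment(out.header)
                a.query_name = rs.read_id
                a.flag = 0 if j == 0 else 256
                a.reference_id = tid[hit.target]
                a.reference_start = hit.pos
                a.mapping_quality = 255
                length = hit.end - hit.pos
                a.cigartuples = [(0, length)]
                if j == 0 and rs.seq:
                    a.query_sequence = rs.seq
                a.set_tag("NM", hit.nm)
                out.write(a)


# ---------------------------------------------------------------------------
# coding sequences and expression


def simulate_cds(config: SimulationConfig) -> dict[str, str]:
    """Random coding sequences over the 61 sense codons (no internal stops)."""
    rng = np.random.default_rng(config.seed + 2)
    # biased codon usage so RCU/demand are non-uniform
    weights = rng.dirichlet(np.ones(len(SENSE_CODONS)) * 0.8)
    out = {}
    lo, hi = config.cds_len_codons
    for i in range(config.n_cds):
        n = int(rng.integers(lo, hi + 1))
        codons = rng.choice(SENSE_CODONS, size=n, p=weights)
        out[f"g{i:04d}"] = "".join(codons)
    return out


def simulate_expression(config: SimulationConfig, gene_ids) -> pd.Series:
    """Log-normal mRNA abundances (linear scale)."""
    rng = np.random.default_rng(config.seed + 3)
    vals = rng.lognormal(config.expression_mu, config.expression_sigma, len(gene_ids))
    return pd.Series(vals, index=list(gene_ids), name="abundance")


# ---------------------------------------------------------------------------
# cohort tables


def simulate_mlr_cohort(config: SimulationConfig) -> pd.DataFrame:
    """Per-sample methylation/CNA/abundance rows from the declared linear model.

    abundance = beta0 + beta_me * me + beta_cna * cna + N(0, sigma), for
    ``n_isoacceptors`` isoacceptors x ``n_conditions`` conditions with
    ``2 * n_per_group`` samples each.
    """
    rng = np.random.default_rng(config.seed + 4)
    b0, bme, bcna, sigma = config.regression_truth
    isoacceptors = ALL_ANTICODONS[: config.n_isoacceptors]
    conditions = [f"cond{k:02d}" for k in range(config.n_conditions)]
    n = 2 * config.n_per_group
    rows = []
    for cond in conditions:
        for iso in isoacceptors:
            me = rng.uniform(0, 1, n)
            cna = rng.normal(0, 0.5, n)
            noise = rng.normal(0, sigma, n) if sigma > 0 else np.zeros(n)
            abundance = b0 + bme * me + bcna * cna + noise
            for s in range(n):
                rows.append(
                    {
                        "isoacceptor": iso,
                        "condition": cond,
                        "sample_id": f"{cond}_s{s:03d}",
                        "me": me[s],
                        "cna": cna[s],
                        "abundance": abundance[s],
                    }
                )
    return pd.DataFrame(rows)


def simulate_sdaw_matrix(config: SimulationConfig):
    """Samples x 60-codon SDAw matrix with a declared tumor shift.

    Healthy baseline is log-normal around 1; tumor samples have
    ``shifted_codons`` multiplied by ``sdaw_shift``.  Returns
    (matrix, group labels).
    """
    rng = np.random.default_rng(config.seed + 5)
    n = 2 * config.n_per_group
    mat = rng.lognormal(0.0, 0.25, size=(n, len(SDA_CODONS)))
    groups = np.array(["healthy"] * config.n_per_group + ["tumor"] * config.n_per_group)
    df = pd.DataFrame(
        mat, columns=SDA_CODONS, index=[f"s{i:03d}" for i in range(n)]
    )
    for codon in config.shifted_codons:
        df.loc[groups == "tumor", codon] *= config.sdaw_shift
    return df, groups


def simulate_survival(config: SimulationConfig):
    """Exponential survival with the declared hazard ratio between
    SDAw-defined groups.

    Patients below the median of a log-normal per-patient SDAw score
    have hazard ``baseline_hazard * hazard_ratio``; censoring is
    independent exponential tuned to the declared censoring rate in the
    baseline group.  Returns (sdaw series, clinical table).
    """
    rng = np.random.default_rng(config.seed + 6)
    n = config.n_patients
    sdaw = pd.Series(
        rng.lognormal(0.0, 0.3, n), index=[f"p{i:03d}" for i in range(n)], name="sdaw"
    )
    low = sdaw < sdaw.median()
    hazard = np.where(low, config.baseline_hazard * config.hazard_ratio, config.baseline_hazard)
    t_event = rng.exponential(1.0 / hazard)
    if config.censoring_rate > 0:
        c_rate = config.baseline_hazard * config.censoring_rate / (1 - config.censoring_rate)
        t_cens = rng.exponential(1.0 / c_rate, n)
    else:
        t_cens = np.full(n, np.inf)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    clinical = pd.DataFrame({"time": time, "event": event}, index=sdaw.index)
    return sdaw, clinical


# ---------------------------------------------------------------------------
# fixture writer


def write_fixtures(config: SimulationConfig, outdir) -> dict[str, Path]:
    """Generate and write a complete fixture set; returns paths.

    Truth tables are written beside every dataset so recovery tests can
    consume only emitted files.
    """
    from . import reference as ref

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    genome, annotation, gene_truth = simulate_reference(config)
    paths["genome"] = outdir / "genome.fa"
    ref._write_fasta(paths["genome"], sorted(genome.items()))
    paths["annotation"] = outdir / "trnas.txt"
    paths["annotation"].write_text(annotation)
    paths["gene_truth"] = outdir / "gene_truth.tsv"
    gene_truth.to_csv(paths["gene_truth"], sep="\t", index=False)

    genes = ref.parse_trna_annotation(paths["annotation"], genome)
    clusters = ref.build_mature_library(genes)
    pretrnas, masked = ref.build_pretrna_and_mask(genes, genome)
    refdir = outdir / "refdir"
    ref.write_reference(refdir, clusters, pretrnas, masked)
    paths["refdir"] = refdir

    read_sets, read_truth = simulate_reads(
        config, clusters, pretrnas=pretrnas, masked_chrom_len=len(genome["chr1"])
    )
    target_lengths = {c.cluster_id: len(c.mature_seq) for c in clusters}
    target_lengths |= {f"pre_{p.gene_id}": len(p.seq) for p in pretrnas}
    target_lengths |= {name: len(seq) for name, seq in masked.items()}
    paths["sam"] = outdir / "reads.sam"
    write_sam(paths["sam"], read_sets, target_lengths)
    paths["read_truth"] = outdir / "read_truth.tsv"
    read_truth.to_csv(paths["read_truth"], sep="\t", index=False)

    cds = simulate_cds(config)
    paths["cds"] = outdir / "cds.fa"
    ref._write_fasta(paths["cds"], sorted(cds.items()))
    expr = simulate_expression(config, cds.keys())
    paths["expression"] = outdir / "expression.tsv"
    expr.rename_axis("gene_id").to_csv(paths["expression"], sep="\t")

    mlr = simulate_mlr_cohort(config)
    paths["mlr"] = outdir / "mlr_cohort.tsv"
    mlr.to_csv(paths["mlr"], sep="\t", index=False)

    sdaw, groups = simulate_sdaw_matrix(config)
    paths["sdaw"] = outdir / "sdaw_matrix.tsv"
    sdaw.assign(group=groups).rename_axis("sample_id").to_csv(paths["sdaw"], sep="\t")

    surv_sdaw, clinical = simulate_survival(config)
    paths["survival"] = outdir / "survival.tsv"
    clinical.assign(sdaw=surv_sdaw).rename_axis("patient_id").to_csv(
        paths["survival"], sep="\t"
    )
    return paths
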
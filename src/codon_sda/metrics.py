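"""Codon-optimality mathematics: RCU, tAI, RtAI, codon demand, and SDA.

The tRNA adaptation index (tAI) weights every sense codon by the
availability of the tRNAs that can decode it under the wobble rules.
For a codon box XY· the four third-base codons draw on the anticodons
with A, G, U or C at position 34 (the reverse complements of XYT, XYC,
XYA, XYG respectively), each non-Watson-Crick interaction discounted by
a selective constraint from the s-vector

    s = (0, 0, 0, 0, 0.5, 0.5, 0.75, 0.5, 0.5)

(the non-optimised values: s is NOT tuned against expression data, which
would make codon optimality circular).  Slots 1-4 are the Watson-Crick
pairings; slot 5 is G:U, 6 is I:C, 7 is I:A, 8 is U:G; slot 9 is the
prokaryotic lysidine C:A decoding of ATA, carried in the vector but not
applied under the eukaryotic rules used here.  ATG is decoded by the
elongator Met tRNA only (no U:G term).

Raw weights W are max-normalised to w; codons with w == 0 (no decoding
tRNA observed) receive the geometric mean of the nonzero weights, per
the reference tAI convention.  The relative weights Rw renormalise w to
a maximum of 1 within each synonymous (amino-acid) family.

The Supply-to-Demand Adaptation (SDA) compares that family-normalised
supply S_c = Rw_c with the family-normalised, expression-weighted codon
usage demand D_c = CU_c / max(CU within family), where
CU_c = sum_j count(c in gene j) * mRNA_j.  SDAw_c = S_c / D_c is defined
for the 60 codons excluding methionine and stops.  Per-gene tAI, RtAI
and SDA are length-normalised geometric means of the respective weights
over the gene's codons, computed in log space.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .genetics import (
    AA_TO_CODONS,
    CODON_TO_AA,
    NUCLEOTIDES,
    SENSE_CODONS,
    STOP_CODONS,
    codon_to_anticodon,
)

logger = logging.getLogger(__name__)

#: non-optimised selective constraints (G:U, I:C, I:A, U:G discounts)
DEFAULT_S = (0.0, 0.0, 0.0, 0.0, 0.5, 0.5, 0.75, 0.5, 0.5)

#: codons carrying SDA weights: sense codons minus ATG (60 codons)
SDA_CODONS: list[str] = [c for c in SENSE_CODONS if c != "ATG"]


# ---------------------------------------------------------------------------
# codon counting


@dataclass
class CodingSequence:
    """One CDS as an ordered codon list (stop/ambiguous codons flagged)."""

    gene_id: str
    codons: list[str]

    @property
    def length(self) -> int:
        return len(self.codons)


def read_cds(source) -> list[CodingSequence]:
    """Load coding sequences from a FASTA path or a {gene_id: seq} mapping.

    Genes whose length is not divisible by 3 are skipped with a warning;
    a single trailing stop codon is trimmed; codons containing non-ACGT
    characters are dropped with a tally.
    """
    if isinstance(source, Mapping):
        items = list(source.items())
    else:
        from Bio import SeqIO

        items = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(source), "fasta")]
    out: list[CodingSequence] = []
    n_ambiguous = 0
    for gene_id, seq in items:
        seq = seq.upper()
        if len(seq) % 3 != 0:
            logger.warning("gene %s: length %d not divisible by 3, skipped", gene_id, len(seq))
            continue
        codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
        if codons and codons[-1] in STOP_CODONS:
            codons = codons[:-1]
        clean = []
        for c in codons:
            if all(b in NUCLEOTIDES for b in c):
                clean.append(c)
            else:
                n_ambiguous += 1
        out.append(CodingSequence(gene_id=gene_id, codons=clean))
    if n_ambiguous:
        logger.warning("%d codons with ambiguous bases dropped", n_ambiguous)
    return out


def count_codons(cds: Iterable[CodingSequence] | Mapping[str, str] | str) -> pd.DataFrame:
    """Per-gene codon count matrix (genes x 64 codons)."""
    if not isinstance(cds, list) or (cds and not isinstance(cds[0], CodingSequence)):
        cds = read_cds(cds)  # type: ignore[arg-type]
    if not cds:
        raise ValueError("no coding sequences")
    all_codons = sorted(
        n1 + n2 + n3 for n1 in NUCLEOTIDES for n2 in NUCLEOTIDES for n3 in NUCLEOTIDES
    )
    codon_index = {c: i for i, c in enumerate(all_codons)}
    mat = np.zeros((len(cds), len(codon_index)), dtype=np.int64)
    for i, g in enumerate(cds):
        for c in g.codons:
            mat[i, codon_index[c]] += 1
    return pd.DataFrame(mat, index=[g.gene_id for g in cds], columns=sorted(codon_index))


def relative_codon_usage(counts: pd.Series | pd.DataFrame) -> pd.Series:
    """RCU: each sense codon's share of its synonymous family's usage.

    Accepts a pooled count vector or a per-gene matrix (pooled by summing).
    Families with zero total usage yield NaN.
    """
    pooled = counts.sum(axis=0) if isinstance(counts, pd.DataFrame) else counts
    rcu = pd.Series(np.nan, index=SENSE_CODONS, dtype=float)
    for codons in AA_TO_CODONS.values():
        total = sum(float(pooled.get(c, 0)) for c in codons)
        for c in codons:
            rcu[c] = float(pooled.get(c, 0)) / total if total > 0 else np.nan
    return rcu


# ---------------------------------------------------------------------------
# tAI weights


@dataclass
class TAIWeights:
    """Per-codon decoding weights: raw W, max-normalised w, family-relative Rw."""

    s: tuple[float, ...]
    W: dict[str, float]
    w: dict[str, float]
    Rw: dict[str, float]
    zero_replacement: float = 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "amino_acid": {c: CODON_TO_AA[c] for c in self.W},
                "W": self.W,
                "w": self.w,
                "Rw": self.Rw,
            }
        ).rename_axis("codon")


def tai_weights(
    abundance: Mapping[str, float], s: Iterable[float] = DEFAULT_S
) -> TAIWeights:
    """Wobble-weighted decoding weights for the 61 sense codons.

    ``abundance`` maps anticodons (DNA 3-mers) to their supply, typically
    square-root-normalised RPM.  Missing anticodons count as zero supply.
    """
    s = tuple(s)
    if len(s) != 9:
        raise ValueError("s-vector must have 9 entries")
    t = {a: float(v) for a, v in abundance.items()}
    if any(v < 0 for v in t.values()):
        raise ValueError("negative anticodon abundance")
    if not any(v > 0 for v in t.values()):
        raise ValueError("all-zero anticodon abundance")

    def get(anticodon: str) -> float:
        return t.get(anticodon, 0.0)

    p = [1.0 - x for x in s]
    W: dict[str, float] = {}
    for n1 in "TCAG":
        for n2 in "TCAG":
            box = n1 + n2
            a34 = codon_to_anticodon(box + "T")
            g34 = codon_to_anticodon(box + "C")
            u34 = codon_to_anticodon(box + "A")
            c34 = codon_to_anticodon(box + "G")
            W[box + "T"] = p[0] * get(a34) + p[4] * get(g34)
            W[box + "C"] = p[1] * get(g34) + p[5] * get(a34)
            W[box + "A"] = p[2] * get(u34) + p[6] * get(a34)
            W[box + "G"] = p[3] * get(c34) + p[7] * get(u34)
    # elongator Met: decoded by the CAT anticodon only, no U:G wobble term
    W["ATG"] = p[3] * get("CAT")
    for stop in STOP_CODONS:
        del W[stop]

    w_max = max(W.values())
    w = {c: v / w_max for c, v in W.items()}
    nonzero = [v for v in w.values() if v > 0]
    geo = math.exp(sum(math.log(v) for v in nonzero) / len(nonzero))
    w = {c: (v if v > 0 else geo) for c, v in w.items()}

    Rw = relative_tai(w)
    return TAIWeights(s=s, W=W, w=w, Rw=Rw, zero_replacement=geo)


def relative_tai(w: Mapping[str, float]) -> dict[str, float]:
    """Rw: w renormalised to a maximum of 1 within each amino-acid family."""
    Rw: dict[str, float] = {}
    for codons in AA_TO_CODONS.values():
        fam_max = max(w[c] for c in codons)
        for c in codons:
            Rw[c] = w[c] / fam_max
    return Rw


def _geometric_mean_score(
    weights: Mapping[str, float], gene: CodingSequence, skip: frozenset[str]
) -> float:
    """Length-normalised product of per-codon weights, in log space."""
    log_sum = 0.0
    n = 0
    for c in gene.codons:
        if c in skip or c not in weights:
            continue
        v = weights[c]
        if not np.isfinite(v):
            continue
        log_sum += math.log(v)
        n += 1
    if n == 0:
        raise ValueError(f"gene {gene.gene_id}: no scoreable codons")
    return math.exp(log_sum / n)


def gene_tai(weights: TAIWeights | Mapping[str, float], gene: CodingSequence) -> float:
    """tAI of a gene: geometric mean of w over its sense codons."""
    w = weights.w if isinstance(weights, TAIWeights) else weights
    return _geometric_mean_score(w, gene, STOP_CODONS)


def gene_rtai(weights: TAIWeights | Mapping[str, float], gene: CodingSequence) -> float:
    """RtAI of a gene: geometric mean of the family-relative weights Rw."""
    rw = weights.Rw if isinstance(weights, TAIWeights) else weights
    return _geometric_mean_score(rw, gene, STOP_CODONS)


# ---------------------------------------------------------------------------
# demand and SDA


@dataclass
class DemandProfile:
    """Expression-weighted codon usage CU and family-normalised demand D."""

    CU: dict[str, float]
    D: dict[str, float]


def codon_demand(counts: pd.DataFrame, expression: Mapping[str, float]) -> DemandProfile:
    """Transcriptome codon demand: CU_c = sum_j count_cj * mRNA_j.

    ``counts`` is the per-gene codon count matrix; ``expression`` maps
    gene ids to linear-scale mRNA abundance.  Genes absent from either
    side are dropped (inner join, logged); D is CU renormalised to a
    family maximum of 1 over sense codons.
    """
    expr = pd.Series(dict(expression), dtype=float)
    if (expr < 0).any():
        raise ValueError("negative expression values")
    shared = counts.index.intersection(expr.index)
    if len(shared) == 0:
        raise ValueError("no shared gene identifiers between counts and expression")
    dropped = (len(counts) - len(shared)) + (len(expr) - len(shared))
    if dropped:
        logger.info("codon_demand: %d unmatched gene ids dropped", dropped)
    if not (expr.loc[shared] > 0).any():
        raise ValueError("all expression values are zero")
    cu_all = counts.loc[shared].mul(expr.loc[shared], axis=0).sum(axis=0)
    CU = {c: float(cu_all.get(c, 0.0)) for c in SENSE_CODONS}
    D: dict[str, float] = {}
    for codons in AA_TO_CODONS.values():
        fam_max = max(CU[c] for c in codons)
        for c in codons:
            D[c] = CU[c] / fam_max if fam_max > 0 else np.nan
    return DemandProfile(CU=CU, D=D)


@dataclass
class SDAProfile:
    """Supply-to-demand weights for the 60 codons (Met and stops excluded)."""

    SDAw: dict[str, float]
    missing: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"amino_acid": {c: CODON_TO_AA[c] for c in self.SDAw}, "SDAw": self.SDAw}
        ).rename_axis("codon")


def sda_weights(supply: Mapping[str, float], demand: DemandProfile) -> SDAProfile:
    """SDAw_c = S_c / D_c over the 60-codon set.

    ``supply`` is the family-relative tAI weight map Rw.  Codons whose
    demand is zero or undefined are flagged missing (NaN), not infinite.
    """
    sdaw: dict[str, float] = {}
    missing: list[str] = []
    for c in SDA_CODONS:
        d = demand.D.get(c, np.nan)
        if not np.isfinite(d) or d == 0:
            sdaw[c] = np.nan
            missing.append(c)
        else:
            sdaw[c] = float(supply[c]) / d
    return SDAProfile(SDAw=sdaw, missing=missing)


def gene_sda(sda: SDAProfile | Mapping[str, float], gene: CodingSequence) -> float:
    """SDA of a gene: geometric mean of SDAw, Met/stop codons excluded."""
    weights = sda.SDAw if isinstance(sda, SDAProfile) else sda
    return _geometric_mean_score(weights, gene, STOP_CODONS | {"ATG"})


def gene_score_table(
    tai: TAIWeights, sda: SDAProfile, genes: Iterable[CodingSequence]
) -> pd.DataFrame:
    """Per-gene tAI, RtAI and SDA scores as one table."""
    rows = []
    for g in genes:
        rows.append(
            {
                "gene_id": g.gene_id,
                "l_g": g.length,
                "tAI": gene_tai(tai, g),
                "RtAI": gene_rtai(tai, g),
                "SDA": gene_sda(sda, g),
            }
        )
    return pd.DataFrame(rows).set_index("gene_id")
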
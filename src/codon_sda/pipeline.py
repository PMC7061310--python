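"""End-to-end orchestration from a YAML config, with a run manifest.

Stages are individually invocable (the CLI subcommands call the same
library functions); the orchestrated run simply chains them.  Every
output directory receives exactly one ``manifest.json`` recording the
tool version, a config hash, input checksums, timestamps and per-stage
record counts.  No stage mutates its inputs, and reruns with identical
inputs reproduce identical non-timestamp bytes.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, cohort, metrics, modifications, quant, reference


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _collect_inputs(config: dict) -> list[Path]:
    keys = {"genome", "annotation", "sam", "cds", "expression", "matrix", "table"}
    found = []
    for block in config.values():
        if isinstance(block, dict):
            for k, v in block.items():
                if k in keys:
                    found.append(Path(v))
    return found


def run_pipeline(config_path) -> dict:
    """Run the configured stages; returns the manifest dict."""
    config_path = Path(config_path)
    config = yaml.safe_load(config_path.read_text())
    if not isinstance(config, dict) or "outdir" not in config:
        raise ValueError("config must be a mapping with an 'outdir' key")
    inputs = _collect_inputs(config)
    missing = [str(p) for p in inputs if not p.exists()]
    if missing:
        raise FileNotFoundError(f"missing inputs: {', '.join(missing)}")

    outdir = Path(config["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": "codon-sda",
        "version": __version__,
        "config_sha256": hashlib.sha256(config_path.read_bytes()).hexdigest(),
        "inputs": {str(p): _sha256(p) for p in inputs},
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "stages": {},
    }

    refdir = outdir / "refdir"
    if "reference" in config:
        blk = config["reference"]
        genes = reference.parse_trna_annotation(blk["annotation"], blk["genome"])
        clusters = reference.build_mature_library(genes)
        pretrnas, masked = reference.build_pretrna_and_mask(
            genes, blk["genome"], flank_len=int(blk.get("flank", 50))
        )
        reference.write_reference(refdir, clusters, pretrnas, masked)
        manifest["stages"]["reference"] = {
            "genes": len(genes),
            "clusters": len(clusters),
        }
    elif "refdir" in config:
        refdir = Path(config["refdir"])

    profile = None
    if "quant" in config:
        blk = config["quant"]
        index = quant.ReferenceIndex.from_refdir(refdir)
        profile = quant.quantify(blk["sam"], index, sample_id=blk.get("sample_id", "sample"))
        profile.to_dataframe().to_csv(outdir / "isoacceptors.tsv", sep="\t", index=False)
        manifest["stages"]["quant"] = {
            "assigned": profile.total_assigned,
            "ambiguous": profile.discarded_ambiguous,
            "premature": profile.discarded_premature,
            "unmapped": profile.unmapped,
        }

    if "metrics" in config:
        blk = config["metrics"]
        if profile is None:
            raise ValueError("metrics stage requires the quant stage")
        clusters = reference.read_mature_library(refdir)
        special = {c.anticodon for c in clusters if c.is_special}
        supply_in = {
            a: v
            for a, v in quant.sqrt_normalize(profile).items()
            if a not in special
        }
        weights = metrics.tai_weights(supply_in)
        cds = metrics.read_cds(blk["cds"])
        counts = metrics.count_codons(cds)
        expr = pd.read_csv(blk["expression"], sep="\t", index_col=0).iloc[:, 0]
        demand = metrics.codon_demand(counts, expr)
        sda = metrics.sda_weights(weights.Rw, demand)
        table = weights.to_frame()
        table["CU"] = pd.Series(demand.CU)
        table["D"] = pd.Series(demand.D)
        table["SDAw"] = pd.Series(sda.SDAw)
        table.to_csv(outdir / "weights.tsv", sep="\t")
        metrics.gene_score_table(weights, sda, cds).to_csv(
            outdir / "gene_scores.tsv", sep="\t"
        )
        manifest["stages"]["metrics"] = {"genes": len(cds), "sda_codons": len(sda.SDAw)}

    if "modifications" in config:
        blk = config["modifications"]
        clusters = reference.read_mature_library(refdir)
        library = {c.cluster_id: c.mature_seq for c in clusters}
        index = quant.ReferenceIndex.from_refdir(refdir)
        columns = modifications.pileup(blk["sam"], library, index=index)
        sites = modifications.call_sites(
            columns,
            min_depth=int(blk.get("min_depth", 20)),
            min_fraction=float(blk.get("min_fraction", 0.1)),
        )
        sites = modifications.annotate_sites(sites, library)
        pd.DataFrame(
            [
                {
                    "cluster_id": s.cluster_id,
                    "position": s.position,
                    "ref": s.ref_base,
                    "dominant_alt": s.dominant_alt,
                    "alt_fraction": s.alt_fraction,
                    "depth": s.depth,
                    "model_position": s.model_position,
                }
                for s in sites
            ]
        ).to_csv(outdir / "modifications.tsv", sep="\t", index=False)
        manifest["stages"]["modifications"] = {"sites": len(sites)}

    if "differential" in config:
        blk = config["differential"]
        df = pd.read_csv(blk["matrix"], sep="\t", index_col=0)
        groups = df.pop(blk.get("group_col", "group"))
        result = cohort.differential(df, groups, blk["group_a"], blk["group_b"])
        result.to_csv(outdir / "differential.tsv", sep="\t")
        manifest["stages"]["differential"] = {"features": len(result)}

    if "mlr" in config:
        blk = config["mlr"]
        data = pd.read_csv(blk["table"], sep="\t")
        result = cohort.fit_isoacceptor_mlr(data)
        result.to_csv(outdir / "mlr.tsv", sep="\t", index=False)
        p_me, pos_me, neg_me = cohort.coefficient_sign_test(result, "me")
        p_cna, pos_cna, neg_cna = cohort.coefficient_sign_test(result, "cna")
        manifest["stages"]["mlr"] = {
            "models": int((~result["skipped"]).sum()),
            "sign_test_me": {"p": p_me, "n_pos": pos_me, "n_neg": neg_me},
            "sign_test_cna": {"p": p_cna, "n_pos": pos_cna, "n_neg": neg_cna},
        }

    if "survival" in config:
        blk = config["survival"]
        tab = pd.read_csv(blk["table"], sep="\t", index_col=0)
        res = cohort.survival_by_sdaw(
            tab[blk.get("score_col", "sdaw")],
            tab[["time", "event"]],
            fraction=float(blk.get("fraction", 0.4)),
        )
        res.km_low.assign(group="low").pipe(
            lambda lo: pd.concat([lo, res.km_high.assign(group="high")])
        ).to_csv(outdir / "survival_km.tsv", sep="\t", index=False)
        manifest["stages"]["survival"] = {
            "logrank_p": res.logrank_p,
            "n_low": res.n_low,
            "n_high": res.n_high,
        }

    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
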
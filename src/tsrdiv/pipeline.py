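"""End-to-end pipeline runners with manifests for reproducibility checks."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as tio
from .errors import ConfigError
from .expression import (
    compute_tau,
    expressed_fraction,
    splicing_entropy,
    transcripts_vs_genes_fit,
)
from .specificity import (
    classify_population_specific,
    enrichment_odds_ratio,
    leave_one_out_specificity,
    misinitiation_rates,
)
from .tsr import (
    annotate_tsrs,
    call_sample_tsrs,
    expression_matrix,
    merge_consensus,
    nearest_feature_distance,
    presence_matrix,
    score_presence,
)
from .tss import fit_power_law, normalize_to_reference

logger = logging.getLogger("tsrdiv")

__version__ = "0.1.0"


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with path.open("rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()


def _require(config: dict, key: str):
    if key not in config or config[key] is None:
        raise ConfigError(f"pipeline config missing required key {key!r}")
    return config[key]


def write_manifest(
    outdir: Path, config: dict, inputs: list[Path], outputs: list[Path]
) -> dict:
    manifest = {
        "tool": "tsrdiv",
        "version": __version__,
        "config_hash": _config_hash(config),
        "inputs": {str(p): _sha256(Path(p)) for p in inputs},
        "outputs": {
            str(Path(p).relative_to(outdir)): _sha256(Path(p)) for p in outputs
        },
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


def run_tsr_pipeline(config: dict, outdir: str | Path) -> dict:
    """CTSS tracks -> normalization -> TSRs -> consensus -> statistics.

    ``config`` keys: ctss (sample_id -> path), design, annotation, gene_sets
    (name -> path, optional), features (BED3, optional), plus stage
    parameters.  Returns the run manifest.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    params = config.get("params", {})
    ctss_paths = _require(config, "ctss")
    design = tio.read_design(_require(config, "design"))
    annotation = tio.read_gtf(_require(config, "annotation"))
    inputs = [Path(p) for p in ctss_paths.values()]
    inputs += [Path(config["design"]), Path(config["annotation"])]
    outputs: list[Path] = []

    logger.info("stage=normalize n_samples=%d", len(ctss_paths))
    tracks = []
    for sid, path in sorted(ctss_paths.items()):
        raw = tio.read_ctss(path, sample_id=sid)
        fit = fit_power_law(
            raw,
            fit_min=params.get("fit_min", 1),
            fit_max=params.get("fit_max", 1000),
        )
        tracks.append(normalize_to_reference(raw, fit))
    for t in tracks:
        p = outdir / f"{t.sample_id}.normalized.ctss.tsv"
        tio.write_ctss(t, p)
        outputs.append(p)

    logger.info("stage=call_tsr")
    tsr_sets = [
        call_sample_tsrs(
            t,
            min_signal=params.get("min_signal", 2.0),
            max_span=params.get("max_span", 20),
            min_stability=params.get("min_stability", 1.0),
        )
        for t in tracks
    ]
    for ts in tsr_sets:
        p = outdir / f"{ts.sample_id}.tsrs.bed"
        tio.write_tsr_bed(ts, p)
        outputs.append(p)

    logger.info("stage=consensus")
    consensus = merge_consensus(tsr_sets, merge_gap=params.get("merge_gap", 20))
    consensus = score_presence(consensus, tsr_sets, tracks)
    presence = presence_matrix(consensus)
    expr = expression_matrix(consensus)
    for name, df in (("presence", presence), ("expression", expr)):
        p = outdir / f"consensus.{name}.tsv"
        df.to_csv(p, sep="\t", index_label="tsr_id")
        outputs.append(p)
    p = outdir / "consensus.bed"
    tio.write_consensus_bed(consensus, p)
    outputs.append(p)

    logger.info("stage=annotate n_consensus=%d", len(consensus))
    tsr_annot = annotate_tsrs(
        consensus,
        annotation,
        promoter_window=tuple(params.get("promoter_window", (-1000, 100))),
        tts_window=tuple(params.get("tts_window", (-100, 1000))),
    )
    annot_df = pd.DataFrame(
        [dataclasses.asdict(r) for r in tsr_annot.values()]
    ).set_index("tsr_id")
    p = outdir / "consensus.annotation.tsv"
    annot_df.to_csv(p, sep="\t")
    outputs.append(p)

    logger.info("stage=classify")
    labels = classify_population_specific(
        presence, design, min_support=params.get("min_support", 2)
    )
    p = outdir / "labels.tsv"
    labels.rename("label").to_csv(p, sep="\t", index_label="tsr_id")
    outputs.append(p)

    gene_sets = {
        name: tio.read_gene_set(path)
        for name, path in config.get("gene_sets", {}).items()
    }
    inputs += [Path(p) for p in config.get("gene_sets", {}).values()]
    enrich_rows = []
    for name, ids in sorted(gene_sets.items()):
        member = pd.Series(
            {i: tsr_annot[i].nearest_gene_id in ids for i in labels.index}
        )
        try:
            res = enrichment_odds_ratio(labels, member)
        except Exception as exc:  # degenerate synthetic runs
            logger.warning("enrichment for %s skipped: %s", name, exc)
            continue
        enrich_rows.append(
            {"gene_set": name, "a": res.table[0], "b": res.table[1],
             "c": res.table[2], "d": res.table[3], "odds_ratio": res.odds_ratio,
             "ci_low": res.ci_low, "ci_high": res.ci_high, "p": res.p}
        )
    if enrich_rows:
        p = outdir / "enrichment.tsv"
        pd.DataFrame(enrich_rows).to_csv(p, sep="\t", index=False)
        outputs.append(p)

    mis = misinitiation_rates(
        tsr_annot, labels, presence, design,
        promoter_like=tuple(params.get("promoter_like", ("promoter",))),
    )
    p = outdir / "misinitiation_rates.tsv"
    mis["rates"].rename("rate").to_csv(p, sep="\t", index_label="sample_id")
    outputs.append(p)

    logger.info("stage=loo")
    # leave-one-out over samples as 'tissues'
    loo = leave_one_out_specificity(presence)
    p = outdir / "loo.fractions.tsv"
    loo.fractions.to_csv(p, sep="\t", index_label="source")
    outputs.append(p)
    p = outdir / "loo.zscores.tsv"
    loo.zscores.to_csv(p, sep="\t", index_label="source")
    outputs.append(p)

    if config.get("features"):
        features = tio.read_bed3(config["features"])
        inputs.append(Path(config["features"]))
        dist = nearest_feature_distance(consensus, features)
        p = outdir / "feature_distance.tsv"
        pd.Series(dist).rename("distance_bp").to_csv(
            p, sep="\t", index_label="tsr_id"
        )
        outputs.append(p)

    return write_manifest(outdir, config, inputs, outputs)


def run_expression_pipeline(config: dict, outdir: str | Path) -> dict:
    """TPM matrices -> tau/binarization -> expressed fractions -> entropy -> fit."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    params = config.get("params", {})
    gene_matrix = tio.read_matrix(_require(config, "gene_matrix"))
    inputs = [Path(config["gene_matrix"])]
    outputs: list[Path] = []

    logger.info("stage=tau n_genes=%d", gene_matrix.shape[0])
    tau = compute_tau(
        gene_matrix,
        tpm_min=params.get("tpm_min", 1.0),
        tau_min=params.get("tau_min", 0.8),
    )
    tau_df = pd.DataFrame(
        {
            "tau": tau.tau,
            "is_tra": tau.is_tra,
            "expressing_tissues": {
                f: ",".join(ts) for f, ts in tau.expressing_tissues.items()
            },
        }
    )
    p = outdir / "tau.tsv"
    tau_df.to_csv(p, sep="\t", index_label="feature_id")
    outputs.append(p)

    thresholds = params.get("thresholds", [0.5, 1.0, 2.0])
    frac = expressed_fraction(gene_matrix, thresholds)
    p = outdir / "expressed_fraction.genes.tsv"
    frac.to_csv(p, sep="\t", index=False)
    outputs.append(p)

    fit_summary = None
    if config.get("transcript_matrix"):
        tx_matrix = tio.read_matrix(config["transcript_matrix"])
        inputs.append(Path(config["transcript_matrix"]))
        tx_map = tio.read_transcript_map(_require(config, "transcript_map"))
        inputs.append(Path(config["transcript_map"]))
        logger.info("stage=entropy n_transcripts=%d", tx_matrix.shape[0])
        ent = splicing_entropy(
            tx_matrix, tx_map,
            min_expressed_isoforms=params.get("min_expressed_isoforms", 2),
        )
        p = outdir / "splicing_entropy.tsv"
        ent.entropy.to_csv(p, sep="\t", index_label="gene_id")
        outputs.append(p)
        p = outdir / "splicing_entropy.medians.tsv"
        ent.column_medians.rename("median_bits").to_csv(
            p, sep="\t", index_label="column"
        )
        outputs.append(p)

        tx_frac = expressed_fraction(tx_matrix, thresholds)
        p = outdir / "expressed_fraction.transcripts.tsv"
        tx_frac.to_csv(p, sep="\t", index=False)
        outputs.append(p)

        logger.info("stage=tg_fit")
        thr = params.get("fit_threshold", 1.0)
        g_counts = frac[frac.threshold == thr].set_index("column").n_expressed
        t_counts = tx_frac[tx_frac.threshold == thr].set_index("column").n_expressed
        common = [c for c in g_counts.index if c in t_counts.index]
        if len(common) >= 3 and np.std([g_counts[c] for c in common]) > 0:
            points = [(float(g_counts[c]), float(t_counts[c])) for c in common]
            fit = transcripts_vs_genes_fit(points, [pt[0] for pt in points])
            fit_summary = pd.DataFrame(
                {
                    "column": common,
                    "n_genes": [pt[0] for pt in points],
                    "n_transcripts": [pt[1] for pt in points],
                    "predicted": fit.predictions.to_numpy(),
                    "ci_half_width": fit.ci_half_widths.to_numpy(),
                }
            )
            fit_summary.attrs["slope"] = fit.slope
            p = outdir / "transcripts_vs_genes.tsv"
            fit_summary.to_csv(p, sep="\t", index=False)
            outputs.append(p)
        else:
            logger.warning("transcripts~genes fit skipped (needs >=3 varying columns)")

    return write_manifest(outdir, config, inputs, outputs)


def setup_logging(verbose: bool = False) -> None:
    logging.basicConfig(
        stream=sys.stderr,
        level=logging.DEBUG if verbose else logging.INFO,
        format="%(levelname)s %(name)s: %(message)s",
    )
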
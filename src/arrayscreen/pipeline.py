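"""End-to-end orchestration: normalize -> fit controls -> LOD -> hits -> QC.

These functions are the library entry points the command-line interface
wraps; they operate on in-memory tables and return plain dicts/DataFrames
so they compose in scripts and notebooks.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

from arrayscreen.lod import (
    call_hits,
    fit_control_model,
    replicate_concordance,
    screen_qc,
)
from arrayscreen.normalization import PlateNormalizer, summarize_replicates

logger = logging.getLogger(__name__)


def score_screen(
    readouts: pd.DataFrame,
    plate_map,
    cell_line: str = "",
    reference: str = "scrambled",
    lod_method: str = "density",
    lod_threshold: float = 3.0,
    qc_min_separation: float = 3.0,
    qc_alpha: float = 0.01,
) -> dict:
    """Score one cell line's plates: viability, control model, LOD, hits, QC.

    Returns a dict with ``normalized`` (per-well viability), ``summary``
    (per-guide means), ``control_model``, ``qc``, ``results`` (hit table
    sorted by LOD) and, when two or more replicates exist,
    ``replicate_concordance`` with Pearson/Spearman correlations.
    """
    value_col = f"viability_vs_{reference}"
    normalized = PlateNormalizer(reference=reference).fit_transform(
        readouts, plate_map
    )
    summary = summarize_replicates(
        normalized, value_column=value_col, cell_line=cell_line or None
    )
    pos = normalized.loc[
        normalized["content_type"] == "positive_control", value_col
    ].to_numpy()
    neg = normalized.loc[
        normalized["content_type"] == "scrambled", value_col
    ].to_numpy()
    model = fit_control_model(pos, neg)
    qc = screen_qc(model, min_separation=qc_min_separation, alpha=qc_alpha)

    gene_summary = summary.loc[summary["content_type"] == "gene"]
    results = call_hits(
        gene_summary,
        model,
        threshold=lod_threshold,
        method=lod_method,
        cell_line=cell_line,
    )

    out = {
        "normalized": normalized,
        "summary": summary,
        "control_model": model,
        "qc": qc,
        "results": results,
    }
    reps = sorted(normalized["replicate"].unique())
    if len(reps) >= 2:
        per_rep = []
        for rep in reps[:2]:
            sub = normalized.loc[
                (normalized["replicate"] == rep)
                & (normalized["content_type"] == "gene")
            ]
            per_rep.append(sub.groupby("guide_id")[value_col].mean())
        paired, r, rho = replicate_concordance(per_rep[0], per_rep[1])
        out["replicate_concordance"] = {
            "paired": paired, "pearson_r": r, "spearman_rho": rho,
        }
    return out


def cross_line_tables(results_by_line: dict[str, dict]) -> dict:
    """Fig-style cross-cell-line artifacts: a viability scatter table
    (line A vs line B per-guide means) and a per-gene viability heatmap
    table (genes x cell lines)."""
    lines = list(results_by_line)
    means = {}
    for line in lines:
        s = results_by_line[line]["summary"]
        s = s.loc[s["content_type"].isin(["gene", "scrambled",
                                          "positive_control"])]
        means[line] = s.set_index("guide_id")["mean"]
    scatter = pd.DataFrame(means).dropna()
    heat = {}
    for line in lines:
        res = results_by_line[line]["results"]
        heat[line] = res.set_index("gene_symbol")[
            "mean_normalized_viability"
        ]
    heatmap = pd.DataFrame(heat)
    return {"scatter": scatter, "heatmap": heatmap}


def write_manifest(out_dir, config: dict, inputs: list[str],
                   outputs: list[str], seed: int | None) -> Path:
    """Machine-readable run manifest enabling exact reruns."""
    import arrayscreen

    cfg_json = json.dumps(config, sort_keys=True, default=str)
    manifest = {
        "package": "arrayscreen",
        "version": arrayscreen.__version__,
        "seed": seed,
        "config": config,
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "inputs": inputs,
        "outputs": outputs,
    }
    path = Path(out_dir) / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path
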
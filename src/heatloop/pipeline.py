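"""End-to-end orchestration: simulate -> compartments -> regulatory elements ->
interactions -> TF network -> assays, with per-stage status, logging, a
machine-readable report and content-hash resume.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import compartments as cp
from . import interactions as ix
from . import motifs as mo
from . import regulatory as reg
from .assays import luciferase_activity, relative_interaction_frequency, two_sample_t
from .synth import ARCHETYPES, SynthConfig, generate_dataset

log = logging.getLogger("heatloop")


class MissingInputError(RuntimeError):
    """An optional input is absent; the stage is skipped, not failed."""

STAGES = ["simulate", "compartments", "regulatory", "interactions", "tf_network", "assays"]
DEPS = {
    "simulate": [],
    "compartments": ["simulate"],
    "regulatory": ["simulate"],
    "interactions": ["simulate"],
    "tf_network": ["simulate", "regulatory"],
    "assays": ["simulate"],
}
KNOWN_KEYS = {"simulate", "compartments", "interactions", "regulatory", "assays", "skip_stages"}


def _setup_logging(outdir: Path) -> None:
    log.setLevel(logging.INFO)
    log.handlers.clear()
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s")
    fh = logging.FileHandler(outdir / "pipeline.log")
    sh = logging.StreamHandler()
    for h in (fh, sh):
        h.setFormatter(fmt)
        log.addHandler(h)


def _load_config(config) -> dict:
    if config is None:
        return {}
    if isinstance(config, dict):
        cfg = config
    else:
        import yaml

        with open(config) as fh:
            cfg = yaml.safe_load(fh) or {}
    unknown = set(cfg) - KNOWN_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return cfg


def _stage_hash(cfg: dict, seed: int, stage: str) -> str:
    payload = json.dumps({"cfg": cfg, "seed": seed, "stage": stage}, sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_all(config=None, seed: int = 0, outdir="results", resume: bool = False) -> dict:
    """Run every stage in dependency order and write ``report.json``.

    A stage failure marks its dependents skipped but independent branches
    complete. With ``resume=True``, stages whose config+seed hash matches the
    previous run are reloaded from their output file instead of recomputed.
    Returns the report dict; ``report["failed"]`` is True iff any stage failed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _setup_logging(outdir)
    cfg = _load_config(config)
    log.info("run_all seed=%d outdir=%s", seed, outdir)

    hashes_path = outdir / ".stage_hashes.json"
    old_hashes = json.loads(hashes_path.read_text()) if (resume and hashes_path.exists()) else {}
    new_hashes: dict[str, str] = {}

    report: dict = {"seed": seed, "config": cfg, "stages": {}, "metrics": {}}
    state: dict = {}
    skip = set(cfg.get("skip_stages", []))

    runners = {
        "simulate": _stage_simulate,
        "compartments": _stage_compartments,
        "regulatory": _stage_regulatory,
        "interactions": _stage_interactions,
        "tf_network": _stage_tf_network,
        "assays": _stage_assays,
    }
    for stage in STAGES:
        entry = {"status": "pending", "params": cfg.get(stage, {})}
        bad_dep = next((d for d in DEPS[stage]
                        if report["stages"].get(d, {}).get("status") not in (None, "ok")), None)
        if stage in skip:
            entry["status"], entry["reason"] = "skipped", "skipped by config"
        elif bad_dep:
            entry["status"], entry["reason"] = "skipped", f"dependency {bad_dep} not ok"
        else:
            h = _stage_hash(cfg, seed, stage)
            new_hashes[stage] = h
            out_file = outdir / f"{stage}.json"
            if resume and old_hashes.get(stage) == h and out_file.exists() and stage != "simulate":
                entry["status"] = "ok"
                entry["resumed"] = True
                metrics = json.loads(out_file.read_text())
                report["metrics"].update(metrics)
                log.info("stage %s resumed from %s", stage, out_file)
                # simulate still has to run to feed later stages
            else:
                entry["resumed"] = False
            if not entry.get("resumed"):
                try:
                    log.info("stage %s: start (seed=%d)", stage, seed)
                    metrics = runners[stage](cfg, seed, state, outdir)
                    out_file.write_text(json.dumps(metrics, indent=1, default=float))
                    report["metrics"].update(metrics)
                    entry["status"] = "ok"
                    entry["output"] = str(out_file)
                except MissingInputError as exc:
                    log.warning("stage %s skipped: %s", stage, exc)
                    entry["status"], entry["reason"] = "skipped", f"missing input: {exc}"
                except Exception as exc:  # stage isolation is the point here
                    log.exception("stage %s failed", stage)
                    entry["status"], entry["reason"] = "failed", str(exc)
        report["stages"][stage] = entry
        log.info("stage %s: %s", stage, entry["status"])

    hashes_path.write_text(json.dumps(new_hashes))
    report["failed"] = any(s["status"] == "failed" for s in report["stages"].values())
    (outdir / "report.json").write_text(json.dumps(report, indent=1, default=str))
    return report


# ---------------------------------------------------------------------------
# stages


def _stage_simulate(cfg, seed, state, outdir):
    params = dict(cfg.get("simulate", {}))
    drop_atac = params.pop("drop_atac", False)
    scfg = SynthConfig(**params)
    ds = generate_dataset(scfg, seed=seed)
    if drop_atac:
        ds.peaks = ds.peaks.drop(columns=[c for c in ds.peaks.columns
                                          if c.startswith(("acc_", "accessible_"))])
    state["dataset"] = ds
    (outdir / "truth.json").write_text(ds.truth.to_json())
    return {
        "n_genes": len(ds.genes.df),
        "n_peaks": len(ds.peaks),
        "n_loops": len(ds.truth.loops),
        "depth_per_chromosome": scfg.depth,
    }


def _stage_compartments(cfg, seed, state, outdir):
    ds = state["dataset"]
    truth = ds.truth
    metrics = {}
    saddle_strengths, corners = {}, {}
    recovery = None
    for cond in ("0h", "1h"):
        cm = ds.contacts.get(("HiC", cond))
        if cm is None:
            continue
        oe = cp.oe_by_chrom(cm)
        corr = {c: cp.correlation_map(m) for c, m in oe.items()}
        prof = cp.compartment_pc1(corr, ds.tracks["H3K9ac"])
        sad = cp.saddle(oe, prof)
        saddle_strengths[cond] = sad.strength
        corners[cond] = sad.corner_means
        if cond == "0h":
            if any(prof.degenerate.values()) or truth.amplitude == 0:
                recovery = None
            else:
                tot = ok = 0
                for c, lab in prof.labels.items():
                    unm = lab != 0
                    ok += int((lab[unm] == truth.labels[c][unm]).sum())
                    tot += int(unm.sum())
                recovery = 100.0 * ok / tot if tot else None
    metrics["compartment_recovery_pct"] = recovery if recovery is not None else "NA"
    metrics["saddle_strength"] = saddle_strengths
    metrics["saddle_corners"] = corners
    for cls in ("arm", "pericentromere"):
        for cond in ("0h", "1h"):
            cm = ds.contacts.get(("HiC", cond))
            if cm is None:
                continue
            curve = cp.scaling_curve(cm, cls)
            metrics[f"scaling_slope_{cls}_{cond}"] = curve.slope
    return metrics


def _stage_regulatory(cfg, seed, state, outdir):
    ds = state["dataset"]
    if not any(c.startswith("acc_") for c in ds.peaks.columns):
        raise MissingInputError("ATAC accessibility columns absent from peaks")
    peaks = reg.classify_proximal_distal(ds.peaks, ds.genes)
    peaks = reg.enhancer_signature(peaks, ds.marks) if ds.marks else peaks
    state["peaks"] = peaks
    prox = peaks[peaks["class"] == "proximal"]
    acc_cols = [f"acc_{t}" for t in ("0h", "1h", "6h")]
    profiles = np.log2(prox[acc_cols].to_numpy())
    km = reg.kmeans_timecourse(profiles, k=int(cfg.get("regulatory", {}).get("k", 5)), seed=seed)
    som = reg.som_fit(profiles, grid=(3, 3), epochs=50, seed=seed)
    from sklearn.metrics import adjusted_rand_score

    arch_names = list(ARCHETYPES)
    true_lab = [arch_names.index(ds.truth.archetype_of_peak[i]) for i in prox.index]
    ari = float(adjusted_rand_score(true_lab, km.labels))
    dfp = pd.DataFrame({"unit": som.labels, "true": true_lab})
    pur = dfp.groupby("unit")["true"].agg(lambda s: s.value_counts().iloc[0] / len(s))
    w = dfp.groupby("unit").size()
    purity = float((pur * w).sum() / w.sum())
    sig = peaks["signature"] == "enhancer-like"
    truth_sig = ds.peaks["signature_true"].reindex(peaks.index)
    expr_means = pd.DataFrame({t: ds.expr[[c for c in ds.expr.columns if c.startswith(t)]]
                               .mean(axis=1) for t in ("0h", "1h", "6h")})
    _, conc = reg.atac_expression_concordance(prox, expr_means, acc_cols)
    return {
        "class_counts": peaks["class"].value_counts().to_dict(),
        "kmeans_ari": ari,
        "som_purity": purity,
        "signature_recovered": int((sig & truth_sig).sum()),
        "signature_false_positives": int((sig & ~truth_sig).sum()),
        "signature_planted": int(truth_sig.sum()),
        "concordance_median_rho": conc["median_rho"],
    }


def _stage_interactions(cfg, seed, state, outdir):
    ds = state["dataset"]
    params = cfg.get("interactions", {})
    cm0 = ds.contacts[("CHiC", "0h")]
    cm1 = ds.contacts[("CHiC", "1h")]
    called0 = ix.call_interactions(cm0, 2, 100, correction=params.get("correction", "BH"))
    called1 = ix.call_interactions(cm1, 2, 100, correction=params.get("correction", "BH"))
    diff = ix.differential_interactions(called0, called1, cm0.total_pairs(), cm1.total_pairs(),
                                        cm_a=cm0, cm_b=cm1)
    key = lambda l: (l.chrom, min(l.bin1, l.bin2), max(l.bin1, l.bin2))
    dirs = {(r["chrom"], r["bin1"], r["bin2"]): r["direction"] for _, r in diff.iterrows()}
    gained = [l for l in ds.truth.loops if l.hsfa1a]
    hic1 = ds.contacts.get(("HiC", "1h"), cm1)
    hic0 = ds.contacts.get(("HiC", "0h"), cm0)
    apa1 = ix.apa(hic1, [key(l) for l in gained]) if gained else None
    apa0 = ix.apa(hic0, [key(l) for l in gained]) if gained else None
    ann = ix.annotate_anchors(called1, ds.genes,
                              state.get("peaks", ds.peaks.assign(**{"class": "distal"})))
    hubs = ix.detect_hubs(ann)
    from .io import write_interactions

    write_interactions(called1, outdir / "interactions_1h.tsv")
    metrics = {
        "n_called_0h": int(len(called0)),
        "n_called_1h": int(len(called1)),
        "gained_recovered": int(sum(dirs.get(key(l)) == "gained" for l in gained)),
        "n_gained_planted": len(gained),
        "apa_score_gained_1h": apa1.score if apa1 else "NA",
        "apa_score_gained_0h": apa0.score if apa0 else "NA",
        "promoter_hubs": len(hubs.promoter_hubs),
        "re_hubs": len(hubs.re_hubs),
    }
    return metrics


def _stage_tf_network(cfg, seed, state, outdir):
    ds = state["dataset"]
    peaks = state.get("peaks")
    if peaks is None:   # regulatory stage was resumed from disk
        peaks = reg.classify_proximal_distal(ds.peaks, ds.genes)
    de_rows = []
    for g, plan in ds.truth.de_plan.items():
        for t in ("1h", "6h"):
            if abs(plan[t]) >= 1:
                de_rows.append((g, t, "up" if plan[t] > 0 else "down"))
    de = pd.DataFrame(de_rows, columns=["gene_id", "time", "direction"])
    net = mo.build_tf_network(ds.tf_table, peaks, de, ds.genes, ds.genome)
    sizes = {}
    for t in ("1h", "6h"):
        sizes[t] = sum(1 for _, _, k in net.edges(keys=True) if k == t)
    return {"network_edges_per_time": sizes, "network_nodes": net.number_of_nodes()}


def _stage_assays(cfg, seed, state, outdir):
    ds = state["dataset"]
    summary, bio = relative_interaction_frequency(ds.qpcr)
    wt1 = bio.query("genotype == 'WT' and condition == '1h'")["rif"]
    kd1 = bio.query("genotype == 'hsfa1a-1' and condition == '1h'")["rif"]
    t = two_sample_t(wt1, kd1)
    luc = luciferase_activity(ds.luc)
    fold = summary.query("genotype == 'WT' and condition == '1h'")["mean"].mean()
    return {
        "rif_wt_1h_fold": float(fold),
        "rif_wt_vs_kd_p": t.p,
        "luc_normalized_means": dict(zip(luc["construct"], luc["normalized_mean"])),
    }
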
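"""Age-of-onset gene classification, output writing and the pipeline orchestrator.

The classifier combines three posterior tables — CD vs control within
children, within adults, and CD children vs CD adults — into one category
per gene. Two thresholds are used on the posterior alternative probability:
*significant* means strictly above 0.5 (the equal-cost Bayes rule) while
*reported* means at least 0.5 (a stratum sitting exactly at the boundary
still counts as involved when deciding which stratum is more altered).
"""

from __future__ import annotations

import json
import logging
import platform
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import __version__
from .errors import ConfigurationError, InputError
from .qpcr import (
    delta_ct,
    partition_by_detection,
    read_assay_table,
    read_ct_table,
    read_sample_table,
    relative_expression,
)
from . import bayesmt, detect, refstab, simdata

logger = logging.getLogger(__name__)

CATEGORIES = (
    "similar_both",
    "only_children",
    "only_adults",
    "higher_adults",
    "higher_children",
    "not_altered",
)

#: The four standard comparisons: (name, group A selector, group B selector).
COMPARISONS = {
    "children": ({"status": "CD", "age_group": "child"},
                 {"status": "control", "age_group": "child"}),
    "adults": ({"status": "CD", "age_group": "adult"},
               {"status": "control", "age_group": "adult"}),
    "cd_by_age": ({"status": "CD", "age_group": "child"},
                  {"status": "CD", "age_group": "adult"}),
    "ctrl_by_age": ({"status": "control", "age_group": "child"},
                    {"status": "control", "age_group": "adult"}),
}


def _sig(p: float) -> bool:
    return bool(p > 0.5) if np.isfinite(p) else False


def _reported(p: float) -> bool:
    return bool(p >= 0.5) if np.isfinite(p) else False


def classify_genes(
    posteriors: pd.DataFrame,
    directions: pd.DataFrame | None = None,
    decimals: int | None = None,
) -> pd.DataFrame:
    """Assign each gene one age-of-onset category.

    Parameters
    ----------
    posteriors
        Indexed by gene with columns ``p_child``, ``p_adult``, ``p_diff``
        holding posterior alternative probabilities (NaN = unreported).
    directions
        Optional, indexed by gene with columns ``t_child``/``t_adult``
        (difference of mean dCt, CD minus control); negative means
        up-regulated in CD. Adds ``direction_child``/``direction_adult``
        labels for significant strata.
    decimals
        If given, posteriors are rounded first (useful when reproducing
        tables printed at fixed precision).

    Rules: with S = significant (> 0.5) and R = reported (>= 0.5) —
    if S(p_diff) and R(child) and R(adult): the stratum with the larger
    posterior wins (``higher_adults``/``higher_children``); else if S(p_diff)
    and exactly one stratum is S: that stratum only; without S(p_diff): both
    strata S -> ``similar_both``, one S -> that stratum only, none ->
    ``not_altered``.
    """
    required = {"p_child", "p_adult", "p_diff"}
    if not required <= set(posteriors.columns):
        raise InputError(f"posterior table needs columns {sorted(required)}")
    if directions is not None and not posteriors.index.equals(directions.index):
        missing = posteriors.index.symmetric_difference(directions.index)
        raise InputError(f"gene sets differ between posteriors and directions: "
                         f"{list(missing)}")

    table = posteriors[["p_child", "p_adult", "p_diff"]].astype(float)
    if decimals is not None:
        table = table.round(decimals)

    categories = []
    for gene, row in table.iterrows():
        pc, pa, pd_ = row["p_child"], row["p_adult"], row["p_diff"]
        sig_c, sig_a = _sig(pc), _sig(pa)
        if _sig(pd_) and _reported(pc) and _reported(pa):
            if pc == pa:
                logger.warning("gene %s: strata tie at %.4g; labelled similar_both",
                               gene, pc)
                cat = "similar_both"
            else:
                cat = "higher_adults" if pa > pc else "higher_children"
        elif _sig(pd_) and (sig_c ^ sig_a):
            cat = "only_children" if sig_c else "only_adults"
        elif sig_c and sig_a:
            cat = "similar_both"
        elif sig_c ^ sig_a:
            cat = "only_children" if sig_c else "only_adults"
        else:
            cat = "not_altered"
        categories.append(cat)

    out = table.copy()
    out["category"] = pd.Categorical(categories, categories=CATEGORIES)
    out["altered"] = out["category"] != "not_altered"

    if directions is not None:
        for stratum, pcol, tcol in (
            ("child", "p_child", "t_child"),
            ("adult", "p_adult", "t_adult"),
        ):
            labels = []
            for gene in out.index:
                if _sig(out.at[gene, pcol]) and np.isfinite(directions.at[gene, tcol]):
                    labels.append(
                        "up_in_CD" if directions.at[gene, tcol] < 0 else "down_in_CD"
                    )
                else:
                    labels.append("")
            out[f"direction_{stratum}"] = labels
    return out


def category_counts(classification: pd.DataFrame) -> dict[str, int]:
    counts = classification["category"].value_counts()
    return {c: int(counts.get(c, 0)) for c in CATEGORIES}


def write_tables(
    classification: pd.DataFrame,
    posteriors: Mapping[str, pd.DataFrame],
    out_dir,
) -> dict[str, Path]:
    """Write the classification and per-comparison posterior tables.

    TSV, UTF-8, dot decimal; posterior probabilities at 4 decimals. A JSON
    summary with category counts sits next to the tables.
    """
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise IOError(f"cannot create output directory {out}: {exc}") from exc

    paths: dict[str, Path] = {}
    paths["classification"] = out / "classification.tsv"
    classification.to_csv(paths["classification"], sep="\t", float_format="%.4f")
    for name, table in posteriors.items():
        p = out / f"posterior_{name}.tsv"
        table.to_csv(p, sep="\t", float_format="%.4f")
        paths[f"posterior_{name}"] = p

    counts = category_counts(classification)
    summary = {
        "n_genes": int(len(classification)),
        "category_counts": counts,
        "n_altered": int(classification["altered"].sum()),
    }
    paths["summary"] = out / "summary.json"
    paths["summary"].write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return paths


# ---------------------------------------------------------------------------
# pipeline


def _gene_labels(assays: pd.DataFrame, assay_ids) -> dict[str, str]:
    """Map assay id -> display label (gene symbol, disambiguated per probe)."""
    genes = assays.loc[list(assay_ids), "gene"]
    dup = genes[genes.duplicated(keep=False)]
    return {
        a: (f"{g}|{a}" if a in dup.index else g) for a, g in genes.items()
    }


def run_pipeline(config: Mapping, out_dir, seed: int | None = None) -> dict:
    """Run simulate/load -> filter -> references -> dCt -> tests -> classify.

    ``config`` sections: ``io`` (either ``ct``/``samples``/``assays`` paths
    or absent when ``simulate`` is given), ``simulate`` (SimulationConfig
    fields), ``filters`` (``majority_fraction``), ``refs`` (``k``), ``model``
    (``engine`` eb|gibbs, ``min_per_group``, gibbs settings), ``costs``
    (``c_fp``, ``c_fn``). Returns a dict of computed artifacts; all tables
    are also written under ``out_dir``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    def note(msg, *args):
        line = msg % args if args else msg
        logger.info(line)
        log_lines.append(line)

    io_cfg = dict(config.get("io", {}))
    if "simulate" in config:
        sim_kwargs = dict(config["simulate"])
        if seed is not None:
            sim_kwargs["seed"] = seed
        sim_cfg = simdata.SimulationConfig(**sim_kwargs)
        ct, samples, assays, truth = simdata.generate_dataset(sim_cfg)
        simdata.write_dataset(ct, samples, assays, out / "simulated", truth)
        note("simulated dataset: %d samples x %d assays (seed=%d)",
             ct.n_samples, ct.n_assays, sim_cfg.seed)
    else:
        for key in ("ct", "samples", "assays"):
            if key not in io_cfg:
                raise ConfigurationError(
                    f"config lacks a 'simulate' block and io.{key} is missing"
                )
        ct = read_ct_table(io_cfg["ct"])
        samples = read_sample_table(io_cfg["samples"])
        assays = read_assay_table(io_cfg["assays"])
        note("loaded dataset: %d samples x %d assays", ct.n_samples, ct.n_assays)

    filters = dict(config.get("filters", {}))
    majority = float(filters.get("majority_fraction", 0.5))
    part = partition_by_detection(ct, assays, majority)
    note("detection partition: %d all-undetected, %d majority-undetected, "
         "%d analyzable", len(part.all_undetected), len(part.majority_undetected),
         len(part.analyzable))

    # reference selection among analyzable non-housekeeping assays
    refs_cfg = dict(config.get("refs", {}))
    k = int(refs_cfg.get("k", 2))
    candidates = refs_cfg.get("candidates") or list(part.analyzable)
    strata = samples["status"] + "_" + samples["age_group"]
    genorm = refstab.genorm_rank(ct, candidates)
    normfinder = refstab.normfinder_rank(ct, candidates, strata)
    references = refstab.select_references([genorm, normfinder], k=k)
    note("selected reference assays: %s (%s)", references,
         ", ".join(assays.loc[r, "gene"] for r in references))

    targets = [a for a in part.analyzable if a not in references]
    expr = delta_ct(ct, references, targets)
    labels = _gene_labels(assays, targets)
    expr = expr.rename(columns=labels)
    note("dCt computed for %d target assays", len(targets))

    rel = relative_expression(expr, samples)

    model_cfg = dict(config.get("model", {}))
    engine = model_cfg.get("engine", "eb")
    min_per_group = int(model_cfg.get("min_per_group", 3))
    costs = dict(config.get("costs", {}))
    c_fp = float(costs.get("c_fp", 1.0))
    c_fn = float(costs.get("c_fn", 1.0))

    stats_tables: dict[str, pd.DataFrame] = {}
    decision_tables: dict[str, pd.DataFrame] = {}
    for name, (sel_a, sel_b) in COMPARISONS.items():
        st = bayesmt.group_statistics(expr, samples, sel_a, sel_b,
                                      min_per_group=min_per_group)
        if engine == "gibbs":
            gibbs = bayesmt.fit_two_groups_gibbs(
                st,
                n_iter=int(model_cfg.get("n_iter", 2000)),
                burn_in=int(model_cfg.get("burn_in", 500)),
                seed=int(model_cfg.get("seed", seed or 0)),
            )
            hyper = gibbs.hyper
        else:
            hyper = bayesmt.fit_two_groups_eb(st)
        post = bayesmt.posterior_null(st, hyper)
        dec = bayesmt.decide(post, c_fp=c_fp, c_fn=c_fn)
        dec.insert(0, "t", st["t"])
        dec.insert(1, "se", st["se"])
        dec["direction"] = np.where(
            dec["reject"], np.where(st["t"] < 0, "up_in_A", "down_in_A"), ""
        )
        stats_tables[name] = st
        decision_tables[name] = dec
        note("comparison %s: pi0=%.3f tau2=%.2f, %d/%d rejected", name,
             hyper.pi0, hyper.tau2, int(dec["reject"].sum()), len(dec))

    det_table = detect.detection_tests(
        ct, samples, list(part.majority_undetected)
    ) if part.majority_undetected else pd.DataFrame(
        columns=["assay_id", "stratum", "cd_detected", "cd_undetected",
                 "ctrl_detected", "ctrl_undetected", "p_value"]
    )
    age_table = detect.age_correlation(expr, samples)

    posteriors = pd.DataFrame(
        {
            "p_child": decision_tables["children"]["p_alt"],
            "p_adult": decision_tables["adults"]["p_alt"],
            "p_diff": decision_tables["cd_by_age"]["p_alt"],
        }
    )
    directions = pd.DataFrame(
        {
            "t_child": stats_tables["children"]["t"],
            "t_adult": stats_tables["adults"]["t"],
        }
    )
    classification = classify_genes(posteriors, directions)

    paths = write_tables(classification, decision_tables, out)
    expr.to_csv(out / "delta_ct.tsv", sep="\t", float_format="%.4f")
    rel.to_csv(out / "relative_expression.tsv", sep="\t", float_format="%.4f")
    det_table.to_csv(out / "detection_tests.tsv", sep="\t", index=False,
                     float_format="%.6f")
    age_table.to_csv(out / "age_correlation.tsv", sep="\t", float_format="%.4f")
    stability = pd.DataFrame(
        {"genorm_M": genorm.scores, "genorm_rank": genorm.ranks,
         "normfinder_score": normfinder.scores, "normfinder_rank": normfinder.ranks}
    )
    stability.to_csv(out / "stability.tsv", sep="\t", float_format="%.4f")
    if genorm.v_series is not None:
        genorm.v_series.to_csv(out / "stability_v_series.tsv", sep="\t",
                               float_format="%.4f", header=["V"])

    note("category counts: %s", category_counts(classification))
    run_log = [
        f"ctbayes {__version__} (python {platform.python_version()})",
        f"seed: {seed}",
        f"engine: {engine}; costs: c_fp={c_fp}, c_fn={c_fn}",
        f"majority_fraction: {majority}; min_per_group: {min_per_group}",
    ] + log_lines
    (out / "run.log").write_text("\n".join(run_log) + "\n")

    return {
        "ct": ct,
        "samples": samples,
        "assays": assays,
        "partition": part,
        "references": references,
        "expr": expr,
        "relative_expression": rel,
        "stats": stats_tables,
        "decisions": decision_tables,
        "detection_tests": det_table,
        "age_correlation": age_table,
        "classification": classification,
        "paths": paths,
    }
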
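"""Batch experiments: participation CV, driver ranking, and reporting.

These functions tie the library together the way the CLI drives it:
filter pathways, run the chosen prediction task for a set of graphlet
adjacencies, evaluate per pathway, normalise AUC-PRs within each
(graphlet, mode) stratum, and derive described-pathway sets and their
pairwise Jaccard overlaps.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Mapping, Set
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from .centrality import CentralityVector, GraphletSupportError, \
    graphlet_eigencentrality
from .evaluation import (
    NA,
    EvaluationRecord,
    auc_pr,
    auc_roc,
    described_set,
    jaccard,
    max_f1_positives,
    normalize_auc_pr,
)
from .io import (
    RunConfig,
    read_gene_list,
    read_gmt,
    read_network,
    write_matrix,
    write_records,
)
from .network import Network
from .pathways import PathwayCollection, filter_pathways
from .prediction import (
    make_folds,
    rank_cancer_candidates,
    score_participation_global,
    score_participation_local,
)

logger = logging.getLogger(__name__)

__all__ = [
    "pathway_seed",
    "evaluate_participation",
    "evaluate_driver_ranking",
    "add_normalized",
    "described_by_graphlet",
    "jaccard_matrix",
    "records_to_frame",
    "run_pipeline",
]


def pathway_seed(seed: int, index: int) -> int:
    """Stable per-pathway sub-seed (independent of pathway naming)."""
    return int(np.random.SeedSequence([seed, index]).generate_state(1)[0]
               % (2**31))


def _global_cache(net: Network, g: int) -> CentralityVector | None:
    try:
        return graphlet_eigencentrality(net, g)
    except GraphletSupportError:
        logger.warning("network has no occurrence of G%d", g)
        return None


def evaluate_participation(
    net: Network,
    pathways: PathwayCollection,
    graphlets: Iterable[int] = (0,),
    mode: str = "local",
    iterations: int = 10,
    folds: int = 5,
    seed: int = 42,
) -> list[EvaluationRecord]:
    """Cross-validated participation prediction for every pathway.

    Within each iteration the fold test sets are pooled, one
    AUC-ROC/AUC-PR pair is computed per iteration, and the iteration
    values are averaged into the pathway's record.  A record is NA when
    every iteration was degenerate or single-class.
    """
    records: list[EvaluationRecord] = []
    for g in graphlets:
        cache = _global_cache(net, g) if mode == "global" else None
        for p_idx, (pid, genes) in enumerate(pathways.items()):
            fold_specs = make_folds(
                net, genes, iterations=iterations, k=folds,
                seed=pathway_seed(seed, p_idx), pathway=pid,
            )
            per_iter_roc, per_iter_pr = [], []
            n_pos_tot, n_tot_tot, n_iter_used = 0, 0, 0
            any_scored = False
            for it in range(1, iterations + 1):
                pooled: list[tuple[float, int]] = []
                for fs in (f for f in fold_specs if f.iteration == it):
                    if mode == "local":
                        ts = score_participation_local(net, fs, g)
                    else:
                        if cache is None:
                            ts = None
                        else:
                            ts = score_participation_global(net, fs, g, cache)
                    if ts is None or ts.degenerate:
                        continue
                    for gene, s in ts.scores.items():
                        pooled.append((s, ts.labels[gene]))
                if not pooled:
                    continue
                scores = [s for s, _ in pooled]
                labels = [y for _, y in pooled]
                roc = auc_roc(scores, labels)
                pr = auc_pr(scores, labels)
                if np.isnan(roc) or np.isnan(pr):
                    continue
                any_scored = True
                per_iter_roc.append(roc)
                per_iter_pr.append(pr)
                n_pos_tot += sum(labels)
                n_tot_tot += len(labels)
                n_iter_used += 1
            if any_scored:
                rec = EvaluationRecord(
                    pathway=pid, graphlet=g, mode=mode,
                    auc_roc=float(np.mean(per_iter_roc)),
                    auc_pr=float(np.mean(per_iter_pr)),
                    n_pos=round(n_pos_tot / n_iter_used),
                    n_total=round(n_tot_tot / n_iter_used),
                )
            else:
                rec = EvaluationRecord(
                    pathway=pid, graphlet=g, mode=mode,
                    auc_roc=NA, auc_pr=NA, n_pos=0, n_total=0,
                    degenerate=True,
                )
            records.append(rec)
    return records


def evaluate_driver_ranking(
    net: Network,
    pathways: PathwayCollection,
    drivers: Set[str],
    graphlets: Iterable[int] = (0,),
    mode: str = "global",
) -> tuple[list[EvaluationRecord], dict[int, frozenset[str]]]:
    """Unsupervised within-pathway driver ranking, per graphlet.

    Returns per-pathway records plus, per graphlet, the union over
    pathways of the correctly predicted driver genes (the true
    positives above each pathway's max-F1 threshold).
    """
    records: list[EvaluationRecord] = []
    predicted: dict[int, set[str]] = {}
    for g in graphlets:
        cache = _global_cache(net, g) if mode == "global" else None
        predicted[g] = set()
        for pid, genes in pathways.items():
            if mode == "global" and cache is None:
                records.append(EvaluationRecord(
                    pathway=pid, graphlet=g, mode=mode, auc_roc=NA,
                    auc_pr=NA, n_pos=0, n_total=0, degenerate=True,
                ))
                continue
            res = rank_cancer_candidates(
                net, genes, g, mode, cache=cache, pathway=pid
            )
            labels = {x: int(x in drivers) for x in res.scores}
            n_pos = sum(labels.values())
            n_tot = len(labels)
            if res.degenerate or n_pos == 0 or n_pos == n_tot:
                records.append(EvaluationRecord(
                    pathway=pid, graphlet=g, mode=mode, auc_roc=NA,
                    auc_pr=NA, n_pos=n_pos, n_total=n_tot,
                    degenerate=res.degenerate,
                ))
                continue
            records.append(EvaluationRecord(
                pathway=pid, graphlet=g, mode=mode,
                auc_roc=auc_roc(res.scores, labels),
                auc_pr=auc_pr(res.scores, labels),
                n_pos=n_pos, n_total=n_tot,
            ))
            predicted[g] |= max_f1_positives(res.scores, labels)
    return records, {g: frozenset(s) for g, s in predicted.items()}


def add_normalized(
    records: list[EvaluationRecord],
) -> list[EvaluationRecord]:
    """Fill ``norm_auc_pr`` within each (graphlet, mode) stratum.

    Strata with fewer than two finite AUC-PRs, or with zero spread,
    keep NA normalised scores (with a warning) rather than failing the
    whole batch.
    """
    out = list(records)
    strata: dict[tuple[int, str], list[int]] = {}
    for i, r in enumerate(out):
        strata.setdefault((r.graphlet, r.mode), []).append(i)
    for (g, mode), idxs in strata.items():
        vals = [out[i].auc_pr for i in idxs]
        try:
            norm = normalize_auc_pr(vals)
        except ValueError as exc:
            logger.warning(
                "stratum (G%d, %s): %s; normalized scores left NA",
                g, mode, exc,
            )
            continue
        for i, v in zip(idxs, norm):
            out[i] = replace(out[i], norm_auc_pr=v)
    return out


def described_by_graphlet(
    records: Iterable[EvaluationRecord], threshold: float = 3.0
) -> dict[tuple[int, str], frozenset[str]]:
    """Described-pathway sets per (graphlet, mode) stratum."""
    strata: dict[tuple[int, str], list[EvaluationRecord]] = {}
    for r in records:
        strata.setdefault((r.graphlet, r.mode), []).append(r)
    return {
        key: described_set(rs, threshold=threshold)
        for key, rs in sorted(strata.items())
    }


def jaccard_matrix(sets: Mapping[int, Set[str]]) -> pd.DataFrame:
    """Graphlet x graphlet Jaccard overlap of gene or pathway sets."""
    keys = sorted(sets)
    data = [
        [jaccard(sets[a], sets[b]) for b in keys] for a in keys
    ]
    labels = [f"G{k}" for k in keys]
    return pd.DataFrame(data, index=labels, columns=labels)


def records_to_frame(records: Iterable[EvaluationRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "pathway": r.pathway, "graphlet": r.graphlet,
                "mode": r.mode, "auc_roc": r.auc_roc, "auc_pr": r.auc_pr,
                "norm_auc_pr": r.norm_auc_pr, "n_pos": r.n_pos,
                "n_total": r.n_total, "degenerate": r.degenerate,
            }
            for r in records
        ]
    )


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute one configured run and write its output files.

    Stages: read inputs -> pathway filter -> (participation CV | driver
    ranking) -> evaluation -> stratum normalisation -> described sets
    and Jaccard overlap reports.  Identical config + seed reproduces
    byte-identical outputs.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    config.echo()

    def _stage(name: str, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise RuntimeError(f"[{name}] {exc}") from exc

    net = _stage("read-network", read_network, config.network)
    collection = _stage("read-pathways", read_gmt, config.pathways)
    kept = _stage(
        "filter-pathways", filter_pathways, net, collection,
        config.min_pathway_size, config.max_pathway_size,
    )
    if len(kept) == 0:
        raise RuntimeError("[filter-pathways] no pathway passed the filter")

    outputs: dict[str, Path] = {"config": out_dir / "config.json"}
    if config.task == "participation":
        records = _stage(
            "participation-cv", evaluate_participation,
            net, kept, config.graphlets, config.mode,
            config.iterations, config.folds, config.seed,
        )
        sets_for_overlap: dict[int, frozenset[str]] = {}
    else:
        if not config.labels:
            raise RuntimeError("[rank-drivers] a labels file is required")
        drivers = _stage("read-labels", read_gene_list, config.labels)
        records, predicted = _stage(
            "rank-drivers", evaluate_driver_ranking,
            net, kept, drivers, config.graphlets, config.mode,
        )
        sets_for_overlap = predicted
        genes_path = out_dir / "predicted_genes.tsv"
        with genes_path.open("w") as fh:
            fh.write("graphlet\tgene\n")
            for g in sorted(predicted):
                for gene in sorted(predicted[g]):
                    fh.write(f"G{g}\t{gene}\n")
        outputs["predicted_genes"] = genes_path

    records = _stage("normalize", add_normalized, records)
    results_path = out_dir / "results.tsv"
    write_records(records, results_path)
    outputs["results"] = results_path

    described = described_by_graphlet(
        records, threshold=config.described_threshold
    )
    described_path = out_dir / "described.tsv"
    with described_path.open("w") as fh:
        fh.write("graphlet\tmode\tpathway\n")
        for (g, mode), pids in described.items():
            for pid in sorted(pids):
                fh.write(f"G{g}\t{mode}\t{pid}\n")
    outputs["described"] = described_path

    if config.task == "participation":
        sets_for_overlap = {
            g: pids
            for (g, mode), pids in described.items()
        }
    if len(sets_for_overlap) >= 2:
        jm = jaccard_matrix(sets_for_overlap)
        jm_path = out_dir / "jaccard.tsv"
        write_matrix(jm, jm_path)
        outputs["jaccard"] = jm_path
    return outputs
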
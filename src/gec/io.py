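"""Readers and writers for the plain-text formats the tool consumes.

Formats: two-column edge-list TSV (networks), GMT (pathway gene sets),
one-gene-per-line label lists, and the results/overlap TSVs the
pipeline emits.  Gene identifiers are opaque, case-sensitive strings;
no symbol mapping is attempted.
"""

from __future__ import annotations

import json
import logging
from collections.abc import Iterable
from dataclasses import dataclass, asdict
from pathlib import Path

import pandas as pd

from .evaluation import EvaluationRecord
from .network import Network
from .pathways import PathwayCollection, filter_pathways  # noqa: F401

logger = logging.getLogger(__name__)

__all__ = [
    "read_network",
    "write_network",
    "read_gmt",
    "write_gmt",
    "read_gene_list",
    "write_gene_list",
    "write_records",
    "read_records",
    "write_matrix",
    "RunConfig",
    "filter_pathways",
]


def read_network(path: str | Path) -> Network:
    """Parse a two-column edge-list TSV into a :class:`Network`.

    Lines starting with ``#`` are comments.  Self-loops and
    duplicate/reversed edges are dropped with a logged count; a
    malformed line (fewer than two columns) or an empty file is an
    error naming the line.
    """
    path = Path(path)
    edges: set[frozenset[str]] = set()
    nodes: set[str] = set()
    n_self, n_dup = 0, 0
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2 or not parts[0] or not parts[1]:
                raise ValueError(
                    f"{path}:{lineno}: expected two tab-separated gene "
                    f"identifiers, got {line!r}"
                )
            u, v = parts[0], parts[1]
            if u == v:
                n_self += 1
                continue
            e = frozenset((u, v))
            if e in edges:
                n_dup += 1
                continue
            edges.add(e)
            nodes |= {u, v}
    if not edges and not nodes:
        raise ValueError(f"{path}: no edges found")
    if n_self or n_dup:
        logger.info(
            "%s: dropped %d self-loops and %d duplicate edges",
            path, n_self, n_dup,
        )
    return Network(nodes, (tuple(sorted(e)) for e in edges))


def write_network(net: Network, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# gene1\tgene2\n")
        for u, v in net.edges():
            fh.write(f"{u}\t{v}\n")


def read_gmt(path: str | Path) -> PathwayCollection:
    """Read a GMT file: pathway-ID, description, tab-separated genes."""
    path = Path(path)
    pathways: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT lines need id, description and "
                    f"at least one gene"
                )
            pid, desc, genes = parts[0], parts[1], parts[2:]
            genes = [g for g in genes if g]
            if pid in pathways:
                raise ValueError(f"{path}:{lineno}: duplicate pathway {pid!r}")
            if not genes:
                raise ValueError(f"{path}:{lineno}: pathway {pid!r} is empty")
            pathways[pid] = frozenset(genes)
            descriptions[pid] = desc
    return PathwayCollection(
        pathways=pathways, provenance=str(path), descriptions=descriptions
    )


def write_gmt(collection: PathwayCollection, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for pid, genes in collection.items():
            desc = collection.descriptions.get(pid, "") or "na"
            fh.write("\t".join([pid, desc, *sorted(genes)]) + "\n")


def read_gene_list(path: str | Path) -> frozenset[str]:
    """One gene identifier per line; ``#`` comments and blanks ignored."""
    path = Path(path)
    genes = set()
    with path.open() as fh:
        for raw in fh:
            line = raw.strip()
            if line and not line.startswith("#"):
                genes.add(line)
    return frozenset(genes)


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in sorted(genes)))


_REC_COLUMNS = [
    "pathway", "graphlet", "mode", "auc_roc", "auc_pr", "norm_auc_pr",
    "n_pos", "n_total", "degenerate",
]


def write_records(
    records: Iterable[EvaluationRecord], path: str | Path
) -> None:
    """One row per (pathway, graphlet, mode); NA values stay as 'nan'."""
    rows = [
        {
            "pathway": r.pathway, "graphlet": r.graphlet, "mode": r.mode,
            "auc_roc": repr(float(r.auc_roc)),
            "auc_pr": repr(float(r.auc_pr)),
            "norm_auc_pr": repr(float(r.norm_auc_pr)),
            "n_pos": r.n_pos, "n_total": r.n_total,
            "degenerate": int(r.degenerate),
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=_REC_COLUMNS).to_csv(
        path, sep="\t", index=False
    )


def read_records(path: str | Path) -> list[EvaluationRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"pathway": str})
    out = []
    for row in df.itertuples(index=False):
        out.append(
            EvaluationRecord(
                pathway=str(row.pathway),
                graphlet=int(row.graphlet),
                mode=str(row.mode),
                auc_roc=float(row.auc_roc),
                auc_pr=float(row.auc_pr),
                norm_auc_pr=float(row.norm_auc_pr),
                n_pos=int(row.n_pos),
                n_total=int(row.n_total),
                degenerate=bool(row.degenerate),
            )
        )
    return out


def write_matrix(df: pd.DataFrame, path: str | Path) -> None:
    """Square labelled matrix (e.g. graphlet x graphlet Jaccard) as TSV."""
    df.to_csv(path, sep="\t")


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Echoed as JSON next to the outputs so any result directory is
    self-describing and reproducible.
    """

    network: str
    pathways: str
    out_dir: str
    labels: str | None = None
    task: str = "participation"
    graphlets: tuple[int, ...] = tuple(range(9))
    mode: str = "local"
    iterations: int = 10
    folds: int = 5
    seed: int = 42
    described_threshold: float = 3.0
    enrichment_alpha: float = 0.05
    min_pathway_size: int = 10
    max_pathway_size: int = 100

    def __post_init__(self) -> None:
        self.graphlets = tuple(int(g) for g in self.graphlets)
        if self.task not in ("participation", "drivers"):
            raise ValueError(f"unknown task {self.task!r}")
        if self.mode not in ("local", "global"):
            raise ValueError(f"unknown mode {self.mode!r}")

    def echo(self) -> None:
        out = Path(self.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "config.json").write_text(
            json.dumps(asdict(self), indent=2, sort_keys=True) + "\n"
        )
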
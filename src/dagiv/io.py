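"""Matrix/report file formats shared by the command-line tools.

Matrices travel as delimited text (TSV or CSV, auto-detected) with a
header row of variable names; edge lists as three-column TSV; test reports
as JSON.  Column names are carried through to reports so gene-style
analyses read naturally, but all computation is positional.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .graph import AncestralRelationGraph, HypothesisSpec, write_edge_tsv
from .inference import DPTestReport

__all__ = [
    "read_matrix",
    "write_matrix",
    "parse_hypothesis",
    "format_hypothesis",
    "write_report",
    "arg_to_dot",
]


def read_matrix(path: str | Path, expected_role: str = "Y") -> tuple[np.ndarray, list[str]]:
    """Read a delimited numeric matrix with a header row.

    Delimiter is auto-detected (TSV/CSV); duplicate column names, ragged
    rows and non-numeric cells are rejected with the file named.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
    sep = "\t" if "\t" in header else ","
    names = header.split(sep)
    dups = sorted({c for c in names if names.count(c) > 1})
    if dups:
        raise ValueError(f"{path} ({expected_role}): duplicate column names {dups}")
    df = pd.read_csv(path, sep=sep)
    if list(map(str, df.columns)) != names:
        raise ValueError(f"{path} ({expected_role}): malformed header")
    try:
        mat = df.to_numpy(float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{path} ({expected_role}): non-numeric cells") from exc
    if not np.isfinite(mat).all():
        raise ValueError(f"{path} ({expected_role}): missing or non-finite values")
    return mat, [str(c) for c in df.columns]


def write_matrix(path: str | Path, mat: np.ndarray, names: list[str]) -> None:
    pd.DataFrame(np.asarray(mat), columns=names).to_csv(path, sep="\t", index=False)


def parse_hypothesis(edges: str | None = None, path: str | None = None) -> HypothesisSpec:
    """Parse "k>j[,k>j...]" edge strings or "a>b>c" path strings."""
    if (edges is None) == (path is None):
        raise ValueError("give exactly one of edges= or path=")
    if edges is not None:
        pairs = []
        for tok in edges.split(","):
            k, j = tok.strip().split(">")
            pairs.append((int(k), int(j)))
        return HypothesisSpec(tuple(pairs), mode="edge")
    nodes = [int(t) for t in path.split(">")]
    return HypothesisSpec.from_path(nodes)


def format_hypothesis(h: HypothesisSpec) -> str:
    if h.mode == "pathway":
        nodes = [h.edges[0][0]] + [j for _, j in h.edges]
        return ">".join(str(v) for v in nodes)
    return ",".join(f"{k}>{j}" for k, j in h.edges)


def _report_dict(report: DPTestReport) -> dict:
    d = {
        "lr": report.lr,
        "pvalue": report.pvalue,
        "M_total": report.M_total,
        "M_valid": report.M_valid,
        "method": report.method,
        "per_edge": [dict(e) for e in report.per_edge],
    }
    if report.classification is not None:
        d["classification"] = {
            "nondegenerate_edges": [list(e) for e in report.classification.nondegenerate_edges],
            "degenerate": report.classification.degenerate,
            "regular": report.classification.regular,
        }
    if report.hypothesis is not None:
        d["hypothesis"] = {"edges": [list(e) for e in report.hypothesis.edges],
                           "mode": report.hypothesis.mode}
    return d


def write_report(
    report: DPTestReport,
    arg: AncestralRelationGraph | None,
    outdir: str | Path,
    *,
    seed: int | None = None,
    config_echo: dict | None = None,
    dot: bool = False,
) -> None:
    """JSON report plus edge-list TSVs (and an optional DOT rendering)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    payload = _report_dict(report)
    if seed is not None:
        payload["seed"] = seed
    if config_echo:
        payload["config"] = config_echo
    (outdir / "report.json").write_text(json.dumps(payload, indent=2, default=float) + "\n")
    if arg is not None:
        write_edge_tsv(outdir / "arg_edges.tsv", arg.ancestral_edges,
                       arg.candidate_intervention_edges)
        if dot:
            hyp = report.hypothesis.edges if report.hypothesis else ()
            (outdir / "arg.dot").write_text(arg_to_dot(arg, hyp))


def arg_to_dot(arg: AncestralRelationGraph, hypothesis_edges=()) -> str:
    lines = ["digraph arg {"]
    for k, j in sorted(arg.ancestral_edges):
        lines.append(f'  Y{k} -> Y{j};')
    for l, j in sorted(arg.candidate_intervention_edges):
        lines.append(f'  X{l} -> Y{j} [style=dotted];')
    for k, j in hypothesis_edges:
        lines.append(f'  Y{k} -> Y{j} [color=red, label="H"];')
    lines.append("}")
    return "\n".join(lines) + "\n"
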
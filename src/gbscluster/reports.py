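"""Plain-text (TSV) report rendering for the experimental protocols.

Each report opens with `#`-prefixed metadata lines recording everything
needed to reproduce the run: method(s), distance transform, discretization,
PAM initialization and seed.  Rendering is purely a function of its inputs,
so identical runs produce byte-identical files.
"""

from __future__ import annotations

from .evaluation import PurityReport
from .protocol import KSweepReport, MethodResult, PairwiseReport, SweepCurve

__all__ = [
    "render_metadata",
    "render_sweep_curve",
    "render_method_table",
    "render_pairwise",
    "render_ksweep",
    "render_purity_report",
    "render_ranking",
    "render_subset",
]


def _fmt(p: float | None) -> str:
    return "NC" if p is None else f"{p:.4f}"


def render_metadata(**meta) -> str:
    return "".join(f"# {k}: {v}\n" for k, v in sorted(meta.items()))


def render_sweep_curve(curve: SweepCurve, **meta) -> str:
    out = render_metadata(
        method=curve.method, k=curve.k, transform=curve.transform,
        best_size=curve.best_size, best_purity=f"{curve.best_purity:.4f}", **meta
    )
    out += "size\tpurity\n"
    for size, p in curve.points:
        out += f"{size}\t{p:.4f}\n"
    return out


def render_method_table(results: list[MethodResult], baseline: float | None = None, **meta) -> str:
    """Comparison-table layout: method / number of features / purity."""
    out = render_metadata(**meta)
    out += "method\tn_features\tpurity\n"
    for r in sorted(results, key=lambda r: (-(r.purity or 0.0), r.n_features)):
        out += f"{r.method}\t{r.n_features}\t{_fmt(r.purity)}\n"
    if baseline is not None:
        out += f"all_features\t-\t{baseline:.4f}\n"
    return out


def render_pairwise(report: PairwiseReport, methods, **meta) -> str:
    """Pairwise-subtype layout: one row per pair, purity (subset size) per
    method, all-features baseline in the last column; NC marks a
    single-feature selection for which purity cannot be computed."""
    out = render_metadata(transform=report.transform, k=2, **meta)
    out += "pair\t" + "\t".join(methods) + "\tall_features\n"
    for pair in report.pairs:
        cells = []
        for m in methods:
            r = report.results[pair][m]
            cells.append(f"{_fmt(r.purity)} ({r.n_features})")
        out += (
            f"{pair[0]}+{pair[1]}\t" + "\t".join(cells)
            + f"\t{report.baselines[pair]:.4f}\n"
        )
    return out


def render_ksweep(report: KSweepReport, methods, **meta) -> str:
    out = render_metadata(transform=report.transform, **meta)
    out += "k\t" + "\t".join(methods) + "\tall_features\n"
    for k in report.k_values:
        cells = []
        for m in methods:
            r = report.results[k][m]
            cells.append(f"{_fmt(r.purity)} ({r.n_features})")
        out += f"{k}\t" + "\t".join(cells) + f"\t{report.baselines[k]:.4f}\n"
    return out


def render_purity_report(rep: PurityReport, **meta) -> str:
    """Contingency table plus the purity value."""
    ct = rep.table
    out = render_metadata(**meta)
    out += "cluster\t" + "\t".join(str(c) for c in ct.class_names) + "\ttotal\n"
    for i, cid in enumerate(ct.cluster_ids):
        row = ct.counts[i]
        out += f"{cid}\t" + "\t".join(str(int(v)) for v in row)
        out += f"\t{int(row.sum())}\n"
    out += "total\t" + "\t".join(str(int(v)) for v in ct.class_totals)
    out += f"\t{ct.n}\n"
    out += f"purity\t{rep.exact.numerator}/{rep.exact.denominator}\t{rep.value:.4f}\n"
    return out


def render_ranking(ranking, **meta) -> str:
    out = render_metadata(method=ranking.method, **meta)
    out += "rank\tfeature\tscore\n"
    for i, (f, s) in enumerate(ranking.entries, 1):
        out += f"{i}\t{f}\t{s:.6f}\n"
    return out


def render_subset(subset, **meta) -> str:
    out = render_metadata(method=subset.method, quality=f"{subset.quality:.6f}", **meta)
    out += "feature\n"
    for f in sorted(subset.features):
        out += f"{f}\n"
    return out
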
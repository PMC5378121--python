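"""End-to-end analysis: simulate/load → orthologs → distances → model.

One :func:`run_analysis` call turns a clade (simulated, or supplied as
annotation/hit/alignment files) into the full report: the GOC_250 vs
16S-divergence points table, whole-set and per-category decay fits
with bootstrap CIs, genome-stability indices with permutation and
Tukey–Kramer comparisons, and optionally per-genome selection
indicators, repeat coverages and MUM tables.  Every artifact carries
the config hash and seed, and a rerun with the same config is
bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .annotation import GenomeAnnotation, read_annotation_tsv
from .decay import GeneOrderDecay
from .divergence import DivergenceMatrix, pairwise_divergence_matrix, read_fasta_alignment
from .features import compare_indicator_groups, selection_indicators
from .orthology import best_bidirectional_hits, filter_hits, read_hit_table
from .rearrangement import resampled_estimate
from .repeats import find_exact_repeats, find_mums, mums_to_frame, repeat_coverage
from .simulate import SimulationConfig, evolve_gene_orders, simulate_hit_tables
from .stats import tukey_kramer_hsd

__all__ = ["AnalysisConfig", "AnalysisResult", "run_analysis", "write_report"]


@dataclass
class AnalysisConfig:
    """Inputs, thresholds and seeds for one analysis run."""

    mode: str = "simulate"                     # {"simulate", "files"}
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    # file mode inputs
    annotation_paths: dict[str, str] = field(default_factory=dict)
    hit_dir: Optional[str] = None              # files named A__B.tsv
    alignment_path: Optional[str] = None       # aligned FASTA
    distance_matrix_path: Optional[str] = None  # PHYLIP square, alternative
    labels_path: Optional[str] = None          # species<TAB>R|N
    sequence_paths: dict[str, str] = field(default_factory=dict)
    # thresholds
    min_identity: float = 40.0
    max_length_diff: float = 0.2
    subsample_size: int = 250
    n_resamples: int = 100
    bootstrap_n: int = 0                       # 0 disables CIs
    alpha: float = 0.05
    include_inversions: bool = True
    use_hit_tables: bool = False               # simulate mode: go through BBH
    include_sequence_analyses: bool = False
    repeat_p_threshold: float = 0.001
    mum_min_length: int = 20
    seed: int = 0
    output_dir: Optional[str] = None

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class AnalysisResult:
    config: AnalysisConfig
    points: pd.DataFrame
    fit_all: dict
    fit_categories: dict
    stability: pd.DataFrame
    tests: dict
    indicators: Optional[pd.DataFrame] = None
    indicator_tests: Optional[pd.DataFrame] = None
    repeat_coverage: Optional[pd.DataFrame] = None
    mums: Optional[dict] = None

    def to_json_dict(self) -> dict:
        out = {
            "schema_version": 1,
            "config_hash": self.config.config_hash(),
            "seed": self.config.seed,
            "points": self.points.to_dict(orient="records"),
            "fit_all": self.fit_all,
            "fit_categories": self.fit_categories,
            "stability": self.stability.to_dict(orient="records"),
            "tests": self.tests,
        }
        if self.indicators is not None:
            out["indicators"] = self.indicators.to_dict(orient="records")
        if self.indicator_tests is not None:
            out["indicator_tests"] = self.indicator_tests.to_dict(orient="records")
        if self.repeat_coverage is not None:
            out["repeat_coverage"] = self.repeat_coverage.to_dict(orient="records")
        if self.mums is not None:
            out["mums"] = {k: v.to_dict(orient="records")
                           for k, v in self.mums.items()}
        return out


def _params_dict(results) -> dict:
    p = results.params
    return {
        "f_i": p.f_i, "p": p.p, "sse": p.sse, "fit_mode": p.fit_mode,
        "ci_f_i": list(p.ci_f_i) if p.ci_f_i else None,
        "ci_p": list(p.ci_p) if p.ci_p else None,
        "n_points": len(results.model.points),
    }


def _stage(name: str):
    """Tag exceptions with the pipeline stage that raised them."""
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, _StageError):
                raise _StageError(f"[stage: {name}] {exc}") from exc
            return False
    return _Ctx()


class _StageError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# input assembly
# ---------------------------------------------------------------------------

def _points_from_simulation(config: AnalysisConfig, rng: np.random.Generator):
    clade = evolve_gene_orders(config.sim)
    labels = clade.resistance
    rows = []
    for a, b in clade.pairs():
        if config.use_hit_tables:
            hits_ab, hits_ba = simulate_hit_tables(clade, a, b, rng=rng)
            fa = filter_hits(hits_ab, config.min_identity, config.max_length_diff)
            fb = filter_hits(hits_ba, config.min_identity, config.max_length_diff)
            omap = best_bidirectional_hits(fa, fb)
            # attach true ranks/strands from the simulated gene orders
            true = clade.ortholog_map(a, b)
            keep = pd.Index(true.genes_a).isin(omap.genes_a)
            df = true.to_frame()[np.asarray(keep)]
            from .orthology import OrthologMap
            df["rank_a"] = df["rank_a"].rank().astype(int) - 1
            df["rank_b"] = df["rank_b"].rank().astype(int) - 1
            omap = OrthologMap.from_frame(df)
        else:
            omap = clade.ortholog_map(a, b)
        est = resampled_estimate(
            omap, subsample_size=config.subsample_size,
            n_resamples=config.n_resamples, rng=rng,
            include_inversions=config.include_inversions)
        rows.append({
            "species_a": a, "species_b": b, "x": clade.x(a, b),
            "goc": est.goc_mean, "category": clade.pair_category(a, b),
            "goc_sd": est.goc_sd, "inv_mean": est.inv_mean,
            "inv_normalized": est.inv_normalized, "n_shared": est.n_shared,
        })
    return pd.DataFrame(rows), labels, clade


def _points_from_files(config: AnalysisConfig, rng: np.random.Generator):
    annots = {sp: read_annotation_tsv(p)
              for sp, p in config.annotation_paths.items()}
    if config.labels_path:
        labels = {}
        for line in Path(config.labels_path).read_text().splitlines():
            if line.strip():
                sp, lab = line.split("\t")[:2]
                labels[sp] = lab.strip()
    else:
        labels = {sp: a.resistance for sp, a in annots.items()}
    # unknown-resistance species fall into the nonresistant group
    labels = {sp: ("R" if labels.get(sp) == "R" else "N") for sp in annots}

    if config.distance_matrix_path:
        dmat = DivergenceMatrix.read_phylip(config.distance_matrix_path)
    elif config.alignment_path:
        aln = read_fasta_alignment(config.alignment_path)
        dmat = pairwise_divergence_matrix(aln)
    else:
        raise ValueError("file mode needs an alignment or a distance matrix")

    species = sorted(annots)
    rows = []
    hit_dir = Path(config.hit_dir)
    for i, a in enumerate(species):
        for b in species[i + 1:]:
            hits_ab = read_hit_table(hit_dir / f"{a}__{b}.tsv")
            hits_ba = read_hit_table(hit_dir / f"{b}__{a}.tsv")
            fa = filter_hits(hits_ab, config.min_identity, config.max_length_diff)
            fb = filter_hits(hits_ba, config.min_identity, config.max_length_diff)
            omap = best_bidirectional_hits(fa, fb, annots[a], annots[b])
            est = resampled_estimate(
                omap, subsample_size=config.subsample_size,
                n_resamples=config.n_resamples, rng=rng,
                include_inversions=config.include_inversions)
            cat = "".join(sorted((labels[a], labels[b]), reverse=True))
            rows.append({
                "species_a": a, "species_b": b, "x": dmat.get(a, b),
                "goc": est.goc_mean, "category": cat,
                "goc_sd": est.goc_sd, "inv_mean": est.inv_mean,
                "inv_normalized": est.inv_normalized, "n_shared": est.n_shared,
            })
    return pd.DataFrame(rows), labels, annots


# ---------------------------------------------------------------------------
# main entry points
# ---------------------------------------------------------------------------

def run_analysis(config: AnalysisConfig) -> AnalysisResult:
    rng = np.random.default_rng(config.seed)

    with _stage("inputs"):
        if config.mode == "simulate":
            points, labels, clade = _points_from_simulation(config, rng)
            annots = None
        elif config.mode == "files":
            points, labels, annots = _points_from_files(config, rng)
            clade = None
        else:
            raise ValueError("mode must be 'simulate' or 'files'")

    with _stage("model_fit"):
        model = GeneOrderDecay(points)
        res_all = model.fit()
        if config.bootstrap_n:
            res_all = res_all.bootstrap_ci(n_boot=config.bootstrap_n,
                                           alpha=config.alpha, rng=rng)
        cats = model.fit_categories(mode="fixed_f_i")
        fit_categories = {c: _params_dict(r) for c, r in cats.items()}

    with _stage("stability"):
        stability = res_all.stability_indices()
        stability["resistance"] = stability["species"].map(labels)
        tests = {}
        have_r = (stability["resistance"] == "R").sum() >= 1
        have_n = (stability["resistance"] == "N").sum() >= 1
        if have_r and have_n:
            tests["stability_fisher_pitman_p"] = res_all.stability_comparison(
                labels, rng=rng)
            tests["residual_category_p"] = res_all.residual_category_test(rng=rng)
        groups = {lab: g["value"].tolist()
                  for lab, g in stability.groupby("resistance")
                  if len(g) >= 2}
        if len(groups) >= 2:
            tk = tukey_kramer_hsd(groups, alpha=config.alpha)
            tests["tukey_kramer"] = tk.to_dict(orient="records")

    indicators = indicator_tests = coverage = None
    mums = None
    if config.include_sequence_analyses:
        with _stage("sequence_analyses"):
            indicators, indicator_tests, coverage, mums = _sequence_stages(
                config, labels, clade, annots, rng)

    return AnalysisResult(
        config=config, points=points, fit_all=_params_dict(res_all),
        fit_categories=fit_categories, stability=stability, tests=tests,
        indicators=indicators, indicator_tests=indicator_tests,
        repeat_coverage=coverage, mums=mums,
    )


def _sequence_stages(config, labels, clade, annots, rng):
    from .simulate import simulate_nucleotide_genome

    species = sorted(labels)
    seqs: dict[str, str] = {}
    anns: dict[str, GenomeAnnotation] = {}
    if config.mode == "files":
        from Bio import SeqIO
        for sp in species:
            path = config.sequence_paths.get(sp)
            if path is None:
                continue
            rec = next(SeqIO.parse(path, "fasta"))
            seqs[sp] = str(rec.seq).upper()
            anns[sp] = annots[sp]
    else:
        for sp in species:
            seq, ann = simulate_nucleotide_genome(
                length=50_000, gc=0.5, skew_amp=0.1, oric=0,
                planted_repeats=[(300, "direct", 1)],
                rrna_positions=[1000, 20_000], rng=rng)
            ann = dataclasses.replace(ann, replicon_id=sp,
                                      resistance=labels[sp])
            seqs[sp] = seq
            anns[sp] = ann

    rows, cov_rows = [], []
    ind_by_label = {"R": [], "N": []}
    for sp in species:
        if sp not in seqs:
            continue
        ind = selection_indicators(anns[sp], seqs[sp])
        ind_by_label[labels[sp]].append(ind)
        rows.append({"species": sp, "resistance": labels[sp], **ind.to_dict()})
        reps = find_exact_repeats(seqs[sp], p_threshold=config.repeat_p_threshold)
        cov_rows.append({
            "species": sp,
            "coverage_p_threshold_pct": repeat_coverage(len(seqs[sp]), reps),
        })
    indicators = pd.DataFrame(rows)
    coverage = pd.DataFrame(cov_rows)
    indicator_tests = None
    if len(ind_by_label["R"]) >= 2 and len(ind_by_label["N"]) >= 2:
        indicator_tests = compare_indicator_groups(
            ind_by_label["R"], ind_by_label["N"], alpha=config.alpha)

    mums = {}
    for lab in ("R", "N"):
        group = [sp for sp in species if labels[sp] == lab and sp in seqs]
        if len(group) >= 2:
            a, b = group[:2]
            mums[f"{a}__{b}"] = mums_to_frame(
                find_mums(seqs[a], seqs[b], min_length=config.mum_min_length))
    return indicators, indicator_tests, coverage, mums or None


def write_report(result: AnalysisResult,
                 output_dir: Optional[str | Path] = None,
                 plots: bool = False) -> Path:
    """Write the machine-readable report (JSON + TSVs) to a directory."""
    outdir = Path(output_dir or result.config.output_dir or ".")
    outdir.mkdir(parents=True, exist_ok=True)
    stamp = f"# config_hash={result.config.config_hash()} seed={result.config.seed}\n"

    def _tsv(df: pd.DataFrame, name: str):
        path = outdir / name
        with path.open("w") as fh:
            fh.write(stamp)
            df.to_csv(fh, sep="\t", index=False)

    _tsv(result.points, "points.tsv")
    _tsv(result.stability, "stability.tsv")
    if result.indicators is not None:
        _tsv(result.indicators, "indicators.tsv")
    if result.repeat_coverage is not None:
        _tsv(result.repeat_coverage, "repeat_coverage.tsv")
    if result.mums:
        for pair, df in result.mums.items():
            _tsv(df, f"mums_{pair}.tsv")
    report = outdir / "report.json"
    report.write_text(json.dumps(result.to_json_dict(), indent=1,
                                 default=float))
    if plots:
        _plots(result, outdir)
    return report


def _plots(result: AnalysisResult, outdir: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    colors = {"RR": "black", "RN": "red", "NN": "blue"}
    pts = result.points
    for cat, sub in pts.groupby("category"):
        ax.scatter(sub["x"], sub["goc"], s=14, alpha=0.7,
                   color=colors.get(cat, "gray"), label=cat)
    xs = np.linspace(0, pts["x"].max(), 200)
    for cat, pr in result.fit_categories.items():
        ax.plot(xs, pr["f_i"] + (1 - pr["f_i"]) * np.power(pr["p"], xs),
                color=colors.get(cat, "gray"))
    ax.set_xlabel("16S distance (substitutions/site)")
    ax.set_ylabel("GOC$_{250}$")
    ax.legend()
    fig.tight_layout()
    fig.savefig(outdir / "goc_vs_divergence.png", dpi=150)
    plt.close(fig)
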
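"""End-to-end orchestration of the pipeline stages on disk.

``run_pipeline`` executes simulate -> profile -> score -> qc -> diff ->
fold -> cluster -> rules in dependency order inside an output
directory, recording tool version, config hash and seed in every
tabular output header.  Reruns with the same config and seed are
byte-identical for all tabular outputs.  ``write_report`` tabulates the
run's results, renders the QC and clustering figures, and verifies the
output checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, clustering, dicer, differential, io
from . import profiling, reactivity, secondary, simulate
from .folding import PseudoEnergyParams, fold_constrained

logger = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "profile", "score", "qc", "diff", "fold",
              "cluster", "rules")


@dataclass
class RunConfig:
    """All stage parameters, with defaults matching the method's values."""

    out_dir: str = "run"
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    # simulate
    n_transcripts: int = 50
    stem_len: int = 15
    loop_len: int = 9
    mod_rate_ss: float = 0.02
    mod_rate_ds: float = 0.002
    background_rate: float = 0.002
    depth: int = 2000
    # external inputs (used when the simulate stage is not requested)
    ref_fasta: str | None = None
    nai_sams: tuple[str, ...] = ()
    dmso_sams: tuple[str, ...] = ()
    structures_db: str | None = None
    # profile
    merge_spacer: int = 2
    min_mapq: int = 1
    # score
    min_coverage: int = 1000
    max_background: float = 0.05
    # qc
    qc_window: int = 50
    qc_step: int = 10
    qc_cutoffs: tuple[int, ...] = reactivity.QC_COVERAGE_CUTOFFS
    # diff
    diff_transcripts: int = 100
    diff_total_reads: int = 1_000_000
    # fold
    shape_slope: float = 1.8
    shape_intercept: float = -0.6
    # cluster
    k: int = 3
    # rules
    rule_target: float = 59.0
    rule_tol: float = 1.0
    n_models: int = 50
    model_jitter: float = 0.5

    def config_hash(self) -> str:
        # hash the analysis parameters, not the output location
        data = dataclasses.asdict(self)
        data.pop("out_dir")
        blob = json.dumps(data, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def to_json(self, path) -> None:
        Path(path).write_text(
            json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        data = json.loads(Path(path).read_text())
        for key in ("stages", "nai_sams", "dmso_sams", "qc_cutoffs"):
            if key in data and data[key] is not None:
                data[key] = tuple(data[key])
        return cls(**data)

    def validate(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if "profile" in self.stages and "simulate" not in self.stages:
            if not self.nai_sams or not self.dmso_sams or not self.ref_fasta:
                raise ValueError(
                    "profile stage without simulate needs ref_fasta, "
                    "nai_sams and dmso_sams")
            for p in (self.ref_fasta, *self.nai_sams, *self.dmso_sams):
                if not Path(p).exists():
                    raise FileNotFoundError(f"missing input: {p}")


def _meta(config: RunConfig) -> dict[str, object]:
    return {"tool": f"icshapemap {__version__}",
            "config": config.config_hash(), "seed": config.seed}


class PipelineRun:
    """Holds on-disk layout plus in-memory stage products."""

    def __init__(self, config: RunConfig):
        self.config = config
        self.dir = Path(config.out_dir)
        self.references: dict[str, str] = {}
        self.structures: dict[str, secondary.SecondaryStructure] = {}
        self.counts: dict[str, dict[str, profiling.MutationCounts]] = {}
        self.profiles: dict[str, reactivity.ReactivityProfile] = {}
        self.folded: dict[str, secondary.SecondaryStructure] = {}

    def path(self, name: str) -> Path:
        return self.dir / name


def _stage_simulate(run: PipelineRun) -> None:
    cfg = run.config
    spec = simulate.SimSpec(
        n_transcripts=cfg.n_transcripts, stem_len=cfg.stem_len,
        loop_len=cfg.loop_len, mod_rate_ss=cfg.mod_rate_ss,
        mod_rate_ds=cfg.mod_rate_ds, background_rate=cfg.background_rate,
        depth=cfg.depth, seed=cfg.seed)
    hairpins = simulate.make_hairpin_set(spec)
    run.references = {name: seq for name, seq, _ in hairpins}
    run.structures = {
        name: secondary.SecondaryStructure.from_dotbracket(seq, db)
        for name, seq, db in hairpins}
    io.write_fasta(run.path("references.fasta"), run.references)
    io.write_dotbracket(run.path("structures.db"),
                        {n: (s, d) for n, s, d in hairpins})
    for rep in (1, 2):
        for condition in ("NAI", "DMSO"):
            reads = []
            for name, seq, db in hairpins:
                rng = np.random.default_rng(
                    (cfg.seed, rep, 1 if condition == "NAI" else 2,
                     int(hashlib.sha1(name.encode()).hexdigest()[:6], 16)))
                reads.extend(simulate.simulate_map_reads(
                    seq, db, spec, condition, name=name, rng=rng))
            simulate.write_sam(run.path(f"{condition.lower()}_rep{rep}.sam"),
                               run.references, reads)


def _stage_profile(run: PipelineRun) -> None:
    cfg = run.config
    if not run.references:
        run.references = io.read_fasta(cfg.ref_fasta)
        if cfg.structures_db:
            run.structures = {
                n: secondary.SecondaryStructure.from_dotbracket(s, d)
                for n, (s, d) in io.read_dotbracket(cfg.structures_db).items()}
    sams = {
        "nai_rep1": run.path("nai_rep1.sam"), "nai_rep2": run.path("nai_rep2.sam"),
        "dmso_rep1": run.path("dmso_rep1.sam"), "dmso_rep2": run.path("dmso_rep2.sam"),
    } if "simulate" in cfg.stages else {
        **{f"nai_rep{i + 1}": p for i, p in enumerate(cfg.nai_sams)},
        **{f"dmso_rep{i + 1}": p for i, p in enumerate(cfg.dmso_sams)},
    }
    for label, sam_path in sams.items():
        counts = profiling.count_mutations_sam(
            sam_path, run.references, merge_spacer=cfg.merge_spacer,
            min_mapq=cfg.min_mapq)
        run.counts[label] = counts
        df = pd.concat([c.to_frame() for c in counts.values()],
                       ignore_index=True)
        io.write_tsv(df, run.path(f"counts_{label}.tsv"), _meta(cfg))


def _stage_score(run: PipelineRun) -> None:
    cfg = run.config
    rows = []
    shape_dir = run.path("shape")
    shape_dir.mkdir(exist_ok=True)
    for name, seq in run.references.items():
        profile = reactivity.score_transcript(
            run.counts["nai_rep1"][name], run.counts["dmso_rep1"][name],
            seq, nai2=run.counts.get("nai_rep2", {}).get(name),
            dmso2=run.counts.get("dmso_rep2", {}).get(name),
            min_coverage=cfg.min_coverage, max_background=cfg.max_background)
        run.profiles[name] = profile
        io.write_shape(shape_dir / f"{name}.shape", profile.scores)
        for pos in range(len(seq)):
            rows.append((name, pos + 1, profile.scores[pos],
                         profile.coverage[pos],
                         profile.norm_factor if profile.norm_factor else np.nan))
    df = pd.DataFrame(rows, columns=["transcript", "position", "score",
                                     "coverage", "norm_factor"])
    io.write_tsv(df, run.path("reactivity.tsv"), _meta(cfg))


def _stage_qc(run: PipelineRun) -> None:
    cfg = run.config
    names = list(run.references)
    rep1 = [run.counts["nai_rep1"][n] for n in names]
    rep2 = [run.counts["nai_rep2"][n] for n in names]
    result = reactivity.replicate_correlation(
        rep1, rep2, window=cfg.qc_window, step=cfg.qc_step,
        cutoffs=cfg.qc_cutoffs, seed=cfg.seed)
    rows = [(cutoff, i, r) for cutoff, rs in result.items()
            for i, r in enumerate(rs)]
    io.write_tsv(pd.DataFrame(rows, columns=["cutoff", "window", "pearson_r"]),
                 run.path("qc_replicates.tsv"), _meta(cfg))


def _stage_diff(run: PipelineRun) -> None:
    cfg = run.config
    rng = np.random.default_rng((cfg.seed, 7001))
    for label, salt in (("enrich", 1), ("cleave", 2)):
        effects = rng.normal(0.0, 1.0, size=cfg.diff_transcripts)
        table = simulate.simulate_count_tables(
            cfg.diff_transcripts, effects, cfg.diff_total_reads,
            seed=int(rng.integers(2 ** 31)))
        scored = differential.score_table(
            table.set_index("transcript")["count_a"],
            table.set_index("transcript")["count_b"])
        scored["true_log2_effect"] = table["true_log2_effect"].to_numpy()
        io.write_tsv(scored, run.path(f"diff_{label}.tsv"), _meta(cfg))


def _stage_fold(run: PipelineRun) -> None:
    cfg = run.config
    params = PseudoEnergyParams(cfg.shape_slope, cfg.shape_intercept)
    folded_records = {}
    compare_rows = []
    for name, seq in run.references.items():
        structure, energy = fold_constrained(seq, run.profiles.get(name),
                                             params)
        run.folded[name] = structure
        folded_records[name] = (seq, structure.to_dotbracket())
        if name in run.structures:
            classes = secondary.compare_structures(structure,
                                                   run.structures[name])
            counts = {c: classes.count(c) for c in set(classes)}
            compare_rows.append({
                "transcript": name, "energy": energy,
                "identical": counts.get(secondary.DIFF_IDENTICAL, 0),
                "ss_in_folded": counts.get(secondary.DIFF_SS_IN_A, 0),
                "ss_in_reference": counts.get(secondary.DIFF_SS_IN_B, 0),
                "different_partner": counts.get(
                    secondary.DIFF_DIFFERENT_PARTNER, 0),
            })
    io.write_dotbracket(run.path("folded.db"), folded_records)
    if compare_rows:
        io.write_tsv(pd.DataFrame(compare_rows),
                     run.path("fold_compare.tsv"), _meta(cfg))


def _stage_cluster(run: PipelineRun) -> None:
    cfg = run.config
    names = [n for n in run.references if n in run.folded]
    profiles = [run.profiles[n] for n in names]
    structures = [run.folded[n] for n in names]
    table, loadings, explained, matrix = clustering.cluster_profiles(
        profiles, structures, k=cfg.k, seed=cfg.seed)
    io.write_tsv(table, run.path("clusters.tsv"),
                 {**_meta(cfg),
                  "explained_variance": ",".join(f"{e:.4f}" for e in explained)})
    loadings = loadings.reset_index(names="position")
    io.write_tsv(loadings, run.path("pca_loadings.tsv"), _meta(cfg))
    io.write_tsv(matrix.reset_index(names="transcript"),
                 run.path("aligned_matrix.tsv"), _meta(cfg))


def _make_rule_fixture(cfg: RunConfig):
    """Synthetic pre-miRNA set for the rules stage.

    Hairpins of 60 nt (26-bp stem, 8-nt loop) on the ideal-helix
    geometry; 3p-miRNA start positions sweep 36..43 so the set spans
    distance- and loop-rule combinations.
    """
    helix = simulate.HelixSpec(n_bp=30)
    stem, loop = 26, 8
    db = "(" * stem + "." * loop + ")" * stem
    spec = simulate.SimSpec(n_transcripts=8, stem_len=stem, loop_len=loop,
                            seed=cfg.seed + 17)
    hairpins = simulate.make_hairpin_set(spec)
    entries = []
    for idx, (name, seq, _) in enumerate(hairpins):
        structure = secondary.SecondaryStructure.from_dotbracket(seq, db)
        p3 = 36 + idx  # 3p miRNA 5' end
        annotation = dicer.MirnaAnnotation(
            name=f"pre_mir_{idx + 1:02d}", sequence=seq,
            span_5p=(1, 22), span_3p=(p3, 60))
        models = simulate.make_model_ensemble(
            helix, cfg.n_models, cfg.model_jitter, seed=cfg.seed + 100 + idx)
        entries.append((annotation, structure, models))
    return entries


def _stage_rules(run: PipelineRun) -> None:
    cfg = run.config
    entries = _make_rule_fixture(cfg)
    table = dicer.rule_table(entries, target=cfg.rule_target,
                             tol=cfg.rule_tol)
    io.write_tsv(table, run.path("dicer_rules.tsv"), _meta(cfg))


_STAGE_FUNCS = {
    "simulate": _stage_simulate, "profile": _stage_profile,
    "score": _stage_score, "qc": _stage_qc, "diff": _stage_diff,
    "fold": _stage_fold, "cluster": _stage_cluster, "rules": _stage_rules,
}


def _write_checksums(run_dir: Path) -> None:
    sums = {}
    for path in sorted(run_dir.rglob("*")):
        if path.is_file() and path.suffix in (".tsv", ".db", ".shape",
                                              ".fasta", ".sam"):
            sums[str(path.relative_to(run_dir))] = hashlib.sha256(
                path.read_bytes()).hexdigest()
    (run_dir / "checksums.json").write_text(json.dumps(sums, indent=2,
                                                       sort_keys=True))


def run_pipeline(config: RunConfig) -> Path:
    """Execute the requested stages; returns the run directory.

    A failing stage leaves completed outputs intact and writes
    ``error.json`` with the stage name and message before re-raising.
    """
    config.validate()
    run = PipelineRun(config)
    run.dir.mkdir(parents=True, exist_ok=True)
    config.to_json(run.path("config.json"))
    ordered = [s for s in ALL_STAGES if s in config.stages]
    for stage in ordered:
        logger.info("stage %s", stage)
        try:
            _STAGE_FUNCS[stage](run)
        except Exception as exc:
            run.path("error.json").write_text(json.dumps(
                {"stage": stage, "error": str(exc)}, indent=2))
            raise
    _write_checksums(run.dir)
    return run.dir


def write_report(run_dir) -> Path:
    """Summarize a finished run into report.md plus figures.

    Verifies output checksums (flagging tampered files), tabulates AUC
    per transcript where the true structures are available, cluster
    sizes, differential-score summaries, and the rule Venn counts, and
    renders the QC cumulative-correlation curves and the cluster
    scatter.
    """
    run_dir = Path(run_dir)
    if not run_dir.exists() or not any(run_dir.iterdir()):
        raise FileNotFoundError(f"empty or missing run directory {run_dir}")
    lines = ["# Pipeline run report", ""]

    bad: set[str] = set()
    sums_path = run_dir / "checksums.json"
    if sums_path.exists():
        sums = json.loads(sums_path.read_text())
        bad = {rel for rel, digest in sums.items()
               if not (run_dir / rel).exists()
               or hashlib.sha256((run_dir / rel).read_bytes()).hexdigest() != digest}
        lines.append(f"Checksums: {len(sums) - len(bad)}/{len(sums)} verified"
                     + (f"; MISMATCH: {', '.join(sorted(bad))}" if bad else ""))
        lines.append("")

    def usable(path: Path) -> bool:
        return path.exists() and path.name not in bad \
            and str(path.relative_to(run_dir)) not in bad

    # per-transcript AUC against the true structures
    react = run_dir / "reactivity.tsv"
    struct_db = run_dir / "structures.db"
    if usable(react) and usable(struct_db):
        df = io.read_tsv(react)
        structures = io.read_dotbracket(struct_db)
        lines.append("## Structure AUC per transcript")
        aucs = []
        for name, grp in df.groupby("transcript"):
            if name not in structures:
                continue
            seq, db = structures[name]
            pt = secondary.pair_table_from_dotbracket(db)
            scores = grp.sort_values("position")["score"].to_numpy()
            try:
                aucs.append((name, reactivity.structure_auc(scores, pt)))
            except ValueError:
                continue
        if aucs:
            vals = np.array([a for _, a in aucs])
            lines.append(f"{len(aucs)} transcripts; mean AUC {vals.mean():.3f}, "
                         f"median {np.median(vals):.3f}")
        lines.append("")

    for label in ("enrich", "cleave"):
        path = run_dir / f"diff_{label}.tsv"
        if usable(path):
            df = io.read_tsv(path)
            lines.append(f"## Differential: {label}")
            lines.append(f"{len(df)} transcripts, "
                         f"{int(df['enriched'].sum())} with score > 0")
            lines.append("")

    clusters_path = run_dir / "clusters.tsv"
    if usable(clusters_path):
        df = io.read_tsv(clusters_path)
        sizes = df["cluster"].value_counts().sort_index()
        lines.append("## Clusters")
        lines.append(", ".join(f"cluster {c}: n={n}" for c, n in sizes.items()))
        lines.append("")

    rules_path = run_dir / "dicer_rules.tsv"
    if usable(rules_path):
        df = io.read_tsv(rules_path)
        lines.append("## Dicer cleavage-site rules (Venn cells)")
        cells = df.groupby(["loop_counting", "three_prime",
                            "five_prime"]).size()
        for (lc, tp, fp), n in cells.items():
            lines.append(f"- loop={bool(lc)} three_prime={bool(tp)} "
                         f"five_prime={bool(fp)}: {n}")
        lines.append("")

    qc_path = run_dir / "qc_replicates.tsv"
    if usable(qc_path):
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        df = io.read_tsv(qc_path)
        fig, ax = plt.subplots(figsize=(5, 4))
        for cutoff, grp in df.groupby("cutoff"):
            rs = np.sort(grp["pearson_r"].to_numpy())
            if rs.size:
                ax.plot(rs, np.linspace(0, 1, rs.size),
                        label=f">{int(cutoff)}x")
        ax.set_xlabel("window Pearson r")
        ax.set_ylabel("cumulative fraction")
        ax.legend(fontsize=7)
        fig.tight_layout()
        fig.savefig(run_dir / "qc_curves.png", dpi=120)
        plt.close(fig)
        lines.append("## Replicate QC")
        med = df.groupby("cutoff")["pearson_r"].median()
        lines.append(", ".join(f">{int(c)}x: median r={m:.3f}"
                               for c, m in med.items()))
        lines.append("See qc_curves.png for the cumulative curves.")
        lines.append("")
    else:
        lines.append("## Replicate QC")
        lines.append("QC stage absent from this run.")
        lines.append("")

    if usable(clusters_path):
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        df = io.read_tsv(clusters_path)
        fig, ax = plt.subplots(figsize=(5, 4))
        for c, grp in df.groupby("cluster"):
            ax.scatter(grp["pc1"], grp["pc2"], s=12, label=f"cluster {c}")
        ax.set_xlabel("PC1")
        ax.set_ylabel("PC2")
        ax.legend(fontsize=7)
        fig.tight_layout()
        fig.savefig(run_dir / "cluster_scatter.png", dpi=120)
        plt.close(fig)

    out = run_dir / "report.md"
    out.write_text("\n".join(lines))
    return out
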
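"""Configuration and orchestration of the full analysis chain.

Stages run in dependency order::

    simulate -> quantify -> diff -> scan -> enrich -> activity -> integrate

Each stage writes plain TSV/FASTA/BED/JSON outputs into the run directory
and can be re-run individually; a manifest records the seed, every
threshold actually applied, per-output checksums and a run hash, so a
rerun with the same config and seed is byte-identical.  One global seed is
fanned out to per-stage seeds through ``numpy.random.SeedSequence.spawn``,
so any stage is reproducible in isolation.

Configs are YAML key-value files; unknown keys are rejected (with a
closest-match suggestion) and thresholds are range-checked before
anything runs.
"""

from __future__ import annotations

import difflib
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import formats, quantify, simulate
from .activity import MotifActivityModel
from .differential import DifferentialAccessibility
from .enrichment import PrerankedGSEA, sets_from_match_matrix
from .integrate import annotate_links, foldchange_correlation, motif_target_enrichment
from .motifscan import MotifMatchMatrix, build_match_matrix, empirical_background, pfm_to_pssm

logger = logging.getLogger("atacmotif.pipeline")

STAGES = ("simulate", "quantify", "diff", "scan", "enrich", "activity", "integrate")

_RANGES = {
    "p_threshold": (0.0, 1.0),
    "fdr_threshold": (0.0, 1.0),
    "gene_fdr_threshold": (0.0, 1.0),
    "scan_p": (0.0, 1.0),
    "alpha": (0.0, 1.0),
    "planting_prob": (0.0, 1.0),
    "gc": (0.0, 1.0),
    "noise_sd": (0.0, float("inf")),
    "dispersion": (0.0, float("inf")),
    "n_perm": (1, 10**7),
    "n_acs": (1, 10**6),
    "n_motifs": (1, 10**4),
    "n_active": (0, 10**4),
    "n_per_group": (2, 100),
    "mean_count": (1.0, 10**6),
}


@dataclass
class PipelineConfig:
    """Fully-defaulted, validated pipeline configuration."""

    outdir: str = "results"
    seed: int = 0
    stages: tuple = STAGES
    # synthetic study
    n_acs: int = 2000
    n_motifs: int = 50
    n_active: int = 10
    planting_prob: float = 0.1
    noise_sd: float = 0.25
    dispersion: float = 0.2
    n_per_group: int = 3
    mean_count: float = 100.0
    gc: float = 0.45
    # thresholds
    p_threshold: float = 0.05
    fdr_threshold: float = 0.2
    scan_p: float = 1e-4
    alpha: float = 0.5
    lambda_rule: str = "min"
    n_perm: int = 2000
    gene_fdr_threshold: float = 0.05
    min_set_size: int = 5
    max_set_size: int = 5000

    def to_dict(self) -> dict:
        d = asdict(self)
        d["stages"] = list(self.stages)
        return d


def validate_config(source) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from a YAML file, dict or None.

    Unknown keys are rejected with a nearest-key suggestion; thresholds
    must lie in their documented ranges; requested stages must be a
    contiguous-order subset of the stage list.
    """
    if source is None:
        raw = {}
    elif isinstance(source, dict):
        raw = dict(source)
    else:
        with open(source, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
    known = set(PipelineConfig.__dataclass_fields__)
    errors = []
    for key in raw:
        if key not in known:
            hint = difflib.get_close_matches(key, known, n=1)
            suffix = f" (did you mean {hint[0]!r}?)" if hint else ""
            errors.append(f"unknown key {key!r}{suffix}")
    for key, bounds in _RANGES.items():
        if key in raw and raw[key] is not None:
            lo, hi = bounds
            try:
                v = float(raw[key])
            except (TypeError, ValueError):
                errors.append(f"{key}: not a number: {raw[key]!r}")
                continue
            if not lo <= v <= hi:
                errors.append(f"{key} = {raw[key]} outside [{lo}, {hi}]")
    if "lambda_rule" in raw and raw["lambda_rule"] not in ("min", "1se"):
        errors.append(f"lambda_rule must be 'min' or '1se', got {raw['lambda_rule']!r}")
    if "stages" in raw:
        bad = [s for s in raw["stages"] if s not in STAGES]
        if bad:
            errors.append(f"unknown stage(s) {bad}; valid: {list(STAGES)}")
        raw["stages"] = tuple(s for s in STAGES if s in raw["stages"])
    if errors:
        raise ValueError("invalid configuration:\n  " + "\n  ".join(errors))
    cfg = PipelineConfig(**raw)
    logger.info("validated config: %s", json.dumps(cfg.to_dict(), sort_keys=True))
    return cfg


def stage_seeds(seed: int) -> dict[str, int]:
    """Deterministic per-stage seeds fanned out from one global seed."""
    children = np.random.SeedSequence(seed).spawn(len(STAGES))
    return {s: int(c.generate_state(1)[0] % (2**31))
            for s, c in zip(STAGES, children)}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class PipelineRun:
    """Executes the stages into one output directory."""

    def __init__(self, config: PipelineConfig, resume: bool = False):
        self.cfg = config
        self.resume = resume
        self.outdir = Path(config.outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.seeds = stage_seeds(config.seed)
        self._study = None

    # -- helpers -----------------------------------------------------------

    def path(self, name: str) -> Path:
        return self.outdir / name

    def _done(self, *names: str) -> bool:
        return self.resume and all(self.path(n).exists() for n in names)

    def _study_data(self):
        if self._study is None:
            cfg = self.cfg
            self._study = simulate.simulate_study(
                n_acs=cfg.n_acs, n_motifs=cfg.n_motifs, n_active=cfg.n_active,
                planting_prob=cfg.planting_prob, noise_sd=cfg.noise_sd,
                dispersion=cfg.dispersion, n_per_group=cfg.n_per_group,
                mean_count=cfg.mean_count, gc=cfg.gc,
                seed=self.seeds["simulate"])
        return self._study

    # -- stages ------------------------------------------------------------

    def stage_simulate(self) -> None:
        names = ("acs.bed", "acs.fasta", "motifs.pfm", "counts_planned.tsv",
                 "samples.tsv", "tss.tsv", "genes.tsv", "truth.json")
        if self._done(*names):
            logger.info("simulate: outputs present, skipping")
            return
        study = self._study_data()
        formats.write_bed_file(study["regions"], self.path("acs.bed"))
        formats.write_fasta_file(study["sequences"], self.path("acs.fasta"))
        formats.write_jaspar_file(study["pwms"], self.path("motifs.pfm"))
        study["counts"].to_csv(self.path("counts_planned.tsv"), sep="\t",
                               index_label="acs_id", lineterminator="\n")
        groups = study["counts"].attrs["groups"]
        pd.DataFrame({"sample": list(groups), "group": list(groups.values())}
                     ).to_csv(self.path("samples.tsv"), sep="\t", index=False,
                              lineterminator="\n")
        frag_dir = self.path("fragments")
        frag_dir.mkdir(exist_ok=True)
        for sample, frags in study["fragments"].items():
            formats.write_bed_file(frags, frag_dir / f"{sample}.bed")
        study["tss_table"].to_csv(self.path("tss.tsv"), sep="\t",
                                  index_label="gene_id", lineterminator="\n")
        study["gene_table"].to_csv(self.path("genes.tsv"), sep="\t",
                                   index_label="gene_id", lineterminator="\n")
        study["truth"].to_json(self.path("truth.json"))

    def stage_quantify(self) -> None:
        if self._done("counts.tsv", "fragment_sizes.tsv"):
            logger.info("quantify: outputs present, skipping")
            return
        acs = formats.read_bed_file(self.path("acs.bed"))
        samples = pd.read_csv(self.path("samples.tsv"), sep="\t")
        frags = {row["sample"]: formats.read_bed_file(
                     self.path("fragments") / f"{row['sample']}.bed")
                 for _, row in samples.iterrows()}
        counts = quantify.count_insertions(frags, acs)
        counts.to_csv(self.path("counts.tsv"), sep="\t", index_label="acs_id",
                      lineterminator="\n")
        all_frags = [f for fl in frags.values() for f in fl]
        quantify.fragment_size_histogram(all_frags, bin_width=10).to_csv(
            self.path("fragment_sizes.tsv"), sep="\t", index=False,
            lineterminator="\n")

    def stage_diff(self) -> None:
        if self._done("differential.tsv"):
            logger.info("diff: outputs present, skipping")
            return
        cfg = self.cfg
        model = DifferentialAccessibility.from_tsv(
            self.path("counts.tsv"), self.path("samples.tsv"))
        res = model.fit(p_threshold=cfg.p_threshold,
                        fdr_threshold=cfg.fdr_threshold)
        logger.info("diff thresholds applied: p < %g, FDR < %g",
                    cfg.p_threshold, cfg.fdr_threshold)
        logger.info("%s", res.summary())
        res.to_tsv(self.path("differential.tsv"))

    def stage_scan(self) -> None:
        if self._done("match_matrix.tsv"):
            logger.info("scan: outputs present, skipping")
            return
        seqs = formats.read_fasta_file(self.path("acs.fasta"))
        pwms = formats.read_jaspar_file(self.path("motifs.pfm"))
        bg = empirical_background(s for _, s in seqs)
        pssms = [pfm_to_pssm(p, background=bg) for p in pwms]
        logger.info("scan threshold applied: p <= %g", self.cfg.scan_p)
        mm = build_match_matrix(seqs, pssms, threshold_p=self.cfg.scan_p)
        mm.to_tsv(self.path("match_matrix.tsv"))

    def stage_enrich(self) -> None:
        if self._done("gsea.tsv"):
            logger.info("enrich: outputs present, skipping")
            return
        diff = pd.read_csv(self.path("differential.tsv"), sep="\t",
                           index_col="acs_id")
        mm = MotifMatchMatrix.from_tsv(self.path("match_matrix.tsv"),
                                       threshold_p=self.cfg.scan_p)
        sig = diff[diff["class"] != "Stable"]
        ranking = sig["log2fc"]
        res = PrerankedGSEA(ranking, sets_from_match_matrix(mm),
                            min_size=self.cfg.min_set_size,
                            max_size=self.cfg.max_set_size).fit(
            n_perm=self.cfg.n_perm, seed=self.seeds["enrich"])
        logger.info("%s", res.summary())
        res.to_tsv(self.path("gsea.tsv"))

    def stage_activity(self) -> None:
        if self._done("activity.tsv", "activity_cv.tsv"):
            logger.info("activity: outputs present, skipping")
            return
        diff = pd.read_csv(self.path("differential.tsv"), sep="\t",
                           index_col="acs_id")
        mm = MotifMatchMatrix.from_tsv(self.path("match_matrix.tsv"),
                                       threshold_p=self.cfg.scan_p)
        res = MotifActivityModel(mm, diff["log2fc"], alpha=self.cfg.alpha).fit(
            rule=self.cfg.lambda_rule, seed=self.seeds["activity"])
        logger.info("%s", res.summary())
        res.to_tsv(self.path("activity.tsv"))
        res.cv_table.to_csv(self.path("activity_cv.tsv"), sep="\t", index=False,
                            lineterminator="\n")

    def stage_integrate(self) -> None:
        if self._done("links.tsv", "target_enrichment.tsv"):
            logger.info("integrate: outputs present, skipping")
            return
        cfg = self.cfg
        acs = formats.read_bed_file(self.path("acs.bed"))
        with open(self.path("tss.tsv"), encoding="utf-8") as fh:
            tss = formats.parse_table(fh, formats.TSS_SCHEMA)
        with open(self.path("genes.tsv"), encoding="utf-8") as fh:
            genes = formats.parse_table(fh, formats.GENE_FC_SCHEMA)
        diff = pd.read_csv(self.path("differential.tsv"), sep="\t",
                           index_col="acs_id")
        mm = MotifMatchMatrix.from_tsv(self.path("match_matrix.tsv"),
                                       threshold_p=cfg.scan_p)
        links = annotate_links(acs, tss, diff, genes,
                               gene_fdr_threshold=cfg.gene_fdr_threshold)
        links.to_csv(self.path("links.tsv"), sep="\t", index_label="acs_id",
                     lineterminator="\n")
        de = list(genes.index[genes["fdr"] < cfg.gene_fdr_threshold])
        activity = pd.read_csv(self.path("activity.tsv"), sep="\t",
                               index_col="motif_id")
        rows = [motif_target_enrichment(m, mm, links, de, list(genes.index))
                for m in activity.index[activity["selected"]]]
        pd.DataFrame(rows).to_csv(self.path("target_enrichment.tsv"), sep="\t",
                                  index=False, lineterminator="\n")
        # knockdown-style anti-correlation check on the linked fold-changes
        linked = links.dropna(subset=["gene_id"])
        acs_fc = diff.loc[linked.index, "log2fc"]
        gene_fc = genes.loc[linked["gene_id"], "log2fc"]
        gene_fc.index = linked.index
        r, p = foldchange_correlation(acs_fc, gene_fc)
        with open(self.path("correlation.tsv"), "w", encoding="utf-8",
                  newline="\n") as fh:
            fh.write("comparison\tr\tp_value\n")
            fh.write(f"acs_vs_gene_log2fc\t{r:.6g}\t{p:.6g}\n")

    # -- driver ------------------------------------------------------------

    def run(self) -> Path:
        t0 = time.time()
        for stage in self.cfg.stages:
            marker = self.path(f"{stage}.failed")
            try:
                getattr(self, f"stage_{stage}")()
            except Exception:
                marker.touch()
                logger.exception("stage %s failed; partial outputs retained", stage)
                raise
            if marker.exists():
                marker.unlink()
        manifest = self._manifest(elapsed=time.time() - t0)
        with open(self.path("manifest.json"), "w", encoding="utf-8",
                  newline="\n") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
            fh.write("\n")
        return self.outdir

    def _manifest(self, elapsed: float) -> dict:
        files = sorted(p for p in self.outdir.rglob("*")
                       if p.is_file() and p.name != "manifest.json")
        checksums = {str(p.relative_to(self.outdir)): _sha256(p) for p in files}
        cfg = self.cfg.to_dict()
        params = {k: v for k, v in cfg.items() if k != "outdir"}
        param_hash = hashlib.sha256(
            json.dumps(params, sort_keys=True).encode()).hexdigest()
        run_hash = hashlib.sha256(
            json.dumps([param_hash, checksums], sort_keys=True).encode()
        ).hexdigest()
        return {"version": __version__, "seed": self.cfg.seed,
                "stage_seeds": self.seeds, "config": cfg,
                "parameter_hash": param_hash, "checksums": checksums,
                "run_hash": run_hash, "elapsed_seconds": round(elapsed, 2)}


def run_pipeline(config=None, resume: bool = False) -> Path:
    """Validate ``config`` (path, dict or None) and execute all stages."""
    cfg = config if isinstance(config, PipelineConfig) else validate_config(config)
    return PipelineRun(cfg, resume=resume).run()


def fixture_config(outdir: str = "results", seed: int = 0, **overrides) -> PipelineConfig:
    """The packaged small study: 1,500 ACS x 40 motifs, 8 active, 3 vs 3.

    Small enough to run end-to-end in a few minutes on one core while
    preserving the study's statistical structure (about 20% differential
    sites, both activator- and repressor-like motifs).
    """
    base = {"outdir": outdir, "seed": seed, "n_acs": 1500, "n_motifs": 40,
            "n_active": 8, "planting_prob": 0.12, "noise_sd": 0.25,
            "dispersion": 0.2, "n_perm": 2000}
    base.update(overrides)
    return validate_config(base)
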
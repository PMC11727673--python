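"""End-to-end pipeline: design -> simulate -> score -> fit -> report.

A :class:`RunConfig` (loadable from YAML, unknown keys rejected) drives
all stages; every artifact is stamped with the config hash and seed, and
a rerun with an identical config is byte-identical.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import __version__, io
from .design import build_questionnaire, generate_bibd, validate_design
from .items import default_catalog, generic_catalog
from .model import compare_subgroups, fit_by_subgroup, fit_maxdiff
from .scoring import count_scores
from .simulate import (
    DEFAULT_HETEROGENEITY_SD,
    PHASES,
    apply_completeness_filter,
    default_profile,
    simulate_study,
    study_emulation,
)

_KNOWN_KEYS = {
    "v", "k", "preset", "strata", "n_submitted_extra", "heterogeneity_sd",
    "estimator", "seed", "layout_seed", "top_m", "outdir",
}


@dataclass
class RunConfig:
    """Configuration for a full simulation-plus-estimation run."""

    v: int = 13
    k: int = 4
    preset: str | None = "study-emulation"
    strata: dict = field(default_factory=dict)     # phase -> n, when no preset
    n_submitted_extra: int = 0
    heterogeneity_sd: float = DEFAULT_HETEROGENEITY_SD
    estimator: str = "maxdiff"                     # maxdiff | sequential
    seed: int = 0
    layout_seed: int | None = None
    top_m: int = 4
    outdir: str = "bwsprefs_run"

    def __post_init__(self) -> None:
        if self.estimator not in ("maxdiff", "sequential"):
            raise ValueError(f"unknown estimator {self.estimator!r}")
        if self.preset is not None and self.preset != "study-emulation":
            raise ValueError(f"unknown preset {self.preset!r}")
        if self.preset is None and not self.strata:
            raise ValueError("either a preset or explicit strata must be given")
        self.seed = int(self.seed)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def config_hash(self) -> str:
        # outdir is excluded: where artifacts land does not change them
        payload = {k: v for k, v in asdict(self).items() if k != "outdir"}
        canon = yaml.safe_dump(payload, sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute every stage and write artifacts to ``config.outdir``.

    Returns a map from artifact name to path.  Stage failures propagate
    with the stage name prefixed.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    log_lines = [f"bwsprefs {__version__} run config_hash={chash} seed={config.seed}"]
    paths: dict[str, Path] = {}

    def stage(name):
        def wrap(fn):
            try:
                return fn()
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        return wrap

    # design
    def _design():
        design = generate_bibd(config.v, config.k)
        report = validate_design(design)
        if not report.passed:
            raise RuntimeError(f"generated design failed validation: {report.violations}")
        log_lines.append(
            f"design: v={design.v} b={design.b} k={design.k} r={design.r} lam={design.lam}"
        )
        return design
    design = stage("design")(_design)

    layout_seed = config.layout_seed if config.layout_seed is not None else config.seed
    catalog = default_catalog() if config.v == 13 else generic_catalog(config.v)
    questionnaire = build_questionnaire(design, layout_seed, catalog)
    paths["design"] = outdir / "design.tsv"
    io.write_design(paths["design"], design, questionnaire.item_ids)
    paths["catalog"] = outdir / "catalog.tsv"
    io.write_catalog(paths["catalog"], catalog)

    # simulate
    def _simulate():
        if config.preset == "study-emulation":
            ds = study_emulation(config.seed, questionnaire, config.heterogeneity_sd)
        else:
            profiles = {
                p: default_profile(p if p in PHASES + ("overall",) else "overall",
                                   config.heterogeneity_sd)
                for p in config.strata
            }
            ds = simulate_study(
                questionnaire, config.strata, profiles,
                n_submitted_extra=config.n_submitted_extra,
                master_seed=config.seed,
            )
        log_lines.append(f"simulate: {len(ds)} submitted respondents")
        return ds
    dataset = stage("simulate")(_simulate)
    paths["responses"] = outdir / "responses.csv"
    io.write_responses(paths["responses"], dataset)

    # filter + score
    included, excluded = apply_completeness_filter(dataset)
    log_lines.append(f"filter: {len(included)} included, {len(excluded)} excluded")
    scores = stage("score")(lambda: count_scores(included))
    paths["scores"] = outdir / "scores.csv"
    io.write_scores(paths["scores"], scores)

    # fit
    def _fit():
        overall = fit_maxdiff(included, likelihood=config.estimator)
        by_phase = (
            fit_by_subgroup(included, likelihood=config.estimator)
            if len(included.strata_counts) >= 2 else {}
        )
        log_lines.append(
            f"fit: overall loglik={overall.llf:.3f} converged={overall.converged} "
            f"iterations={overall.n_iter}"
        )
        return overall, by_phase
    overall, by_phase = stage("fit")(_fit)
    paths["results"] = outdir / "results.csv"
    io.write_results(paths["results"], {"overall": overall, **by_phase})
    paths["plot_data"] = outdir / "plot_data.csv"
    io.write_plot_data(paths["plot_data"], overall)

    # report
    if by_phase:
        table = stage("report")(lambda: compare_subgroups(by_phase, config.top_m))
        paths["comparison"] = outdir / "comparison.csv"
        io.write_comparison(paths["comparison"], table)
        log_lines.append(
            "report: top item per phase "
            + ", ".join(f"{p}={table.top[p].iloc[0]}" for p in table.phases)
        )

    for p in paths.values():  # stamp artifacts with provenance
        _prepend_stamp(p, chash, config.seed)

    paths["log"] = outdir / "run.log"
    paths["log"].write_text("\n".join(log_lines) + "\n")
    return paths


def _prepend_stamp(path: Path, chash: str, seed: int) -> None:
    body = path.read_text()
    stamp = f"# bwsprefs={__version__} config_hash={chash} seed={seed}\n"
    if not body.startswith("# bwsprefs="):
        path.write_text(stamp + body)
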
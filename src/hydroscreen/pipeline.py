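"""End-to-end orchestration: simulate/load → assay → profile → ordinate → screen.

A run is described by a declarative :class:`RunConfig` (YAML on disk,
CLI overrides) and produces a manifest recording the config echo, input
checksums, package version and per-stage log, so identical config +
inputs give byte-identical outputs. All randomness flows from one root
seed, split deterministically per stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from hydroscreen import __version__
from hydroscreen.assay import ActivitySeries, read_activity_series, write_activity_series
from hydroscreen.ordination import correspondence_analysis, ordination_summary, rda
from hydroscreen.profiles import (
    AsvCountTable,
    TaxonomyTable,
    alpha_diversity_table,
    filter_samples,
    read_counts_tsv,
    read_metadata_tsv,
    read_taxonomy_tsv,
    to_relative,
    write_counts_tsv,
    write_taxonomy_tsv,
)
from hydroscreen.screening import ScreenConfig, ScreeningError, screen
from hydroscreen.simulate import CommunitySimSpec, simulate_reactor

logger = logging.getLogger(__name__)

REACTORS = ("R1", "R2", "R3")
ENZYMES = ("cellulase", "xylanase")


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """Declarative description of one pipeline run."""

    outdir: str = "hydroscreen_out"
    seed: int | None = 0
    simulate: bool = True
    reactors: tuple[str, ...] = REACTORS
    enzymes: tuple[str, ...] = ENZYMES
    # input paths (used when simulate=False)
    counts_path: str | None = None
    taxonomy_path: str | None = None
    metadata_path: str | None = None
    activity_path: str | None = None
    # thresholds
    min_reads: int = 10_000
    ks_alpha: float = 0.05
    n_top: int = 25
    min_prevalence: int = 4
    align_tolerance_days: int = 3
    regression: str = "z_on_z"
    rate_r2_threshold: float = 0.98
    independence_tolerance: float = 0.25
    n_permutations: int = 999
    transform: str = "hellinger"
    # synthetic-community overrides
    sim_n_asvs: int = 2000
    sim_n_responders: int = 10
    sim_tracking: float = 0.9

    def validate(self) -> None:
        self.screen_config().validate()
        if not 0 <= self.sim_tracking <= 1:
            raise ConfigError("sim_tracking: must be in [0, 1]")
        if self.transform not in ("hellinger", "none"):
            raise ConfigError(f"transform: unknown {self.transform!r}")
        if self.n_permutations < 0:
            raise ConfigError("n_permutations: must be >= 0")
        if (self.n_permutations or self.simulate) and self.seed is None:
            raise ConfigError("seed: required for simulation or permutation tests")
        if not self.simulate:
            for name in ("counts_path", "metadata_path", "activity_path"):
                if getattr(self, name) is None:
                    raise ConfigError(f"{name}: required when simulate=False")

    def screen_config(self) -> ScreenConfig:
        return ScreenConfig(
            min_reads=self.min_reads,
            ks_alpha=self.ks_alpha,
            min_prevalence=self.min_prevalence,
            n_top=self.n_top,
            align_tolerance_days=self.align_tolerance_days,
            regression=self.regression,
        )

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"config: unknown keys {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        cfg = cls(**data)
        for tup in ("reactors", "enzymes"):
            setattr(cfg, tup, tuple(getattr(cfg, tup)))
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stage_seed(root: int, stage: str) -> int:
    digest = hashlib.sha256(f"{root}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and write outputs + manifest under ``outdir``.

    Returns the manifest dict. Fails fast with a stage-named message on
    missing inputs or schema violations.
    """
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(config).items()},
        "inputs": {},
        "outputs": [],
        "stages": [],
    }

    def _log(stage: str, msg: str) -> None:
        logger.info("[%s] %s", stage, msg)
        manifest["stages"].append({"stage": stage, "message": msg})

    def _emit(name: str, writer) -> Path:
        path = out / name
        writer(path)
        manifest["outputs"].append(name)
        return path

    # ---- stage: inputs -----------------------------------------------------
    tables: dict[str, AsvCountTable] = {}
    taxonomies: dict[str, TaxonomyTable] = {}
    activities: dict[tuple[str, str], ActivitySeries] = {}
    truths = {}
    if config.simulate:
        spec = CommunitySimSpec(
            n_asvs=config.sim_n_asvs,
            n_responders=config.sim_n_responders,
            responder_tracking=config.sim_tracking,
        )
        for i, reactor in enumerate(config.reactors):
            seed = _stage_seed(config.seed, f"simulate:{reactor}")
            series, table, taxonomy, truth = simulate_reactor(
                reactor, seed=seed, community_spec=spec
            )
            tables[reactor] = table
            taxonomies[reactor] = taxonomy
            truths[reactor] = sorted(truth.responder_ids)
            for enz in config.enzymes:
                activities[(reactor, enz)] = series[enz]
            _log("simulate", f"{reactor}: {table.counts.shape[0]} samples × "
                             f"{table.counts.shape[1]} ASVs, seed {seed}")
            _emit(f"counts_{reactor}.tsv", lambda p, t=table: write_counts_tsv(t, p))
            _emit(f"taxonomy_{reactor}.tsv", lambda p, t=taxonomy: write_taxonomy_tsv(t, p))
        manifest["synthetic_truth"] = truths
    else:
        for name in ("counts_path", "taxonomy_path", "metadata_path", "activity_path"):
            p = getattr(config, name)
            if p is not None:
                if not Path(p).exists():
                    raise ConfigError(f"inputs: {name} not found: {p}")
                manifest["inputs"][name] = _sha256(Path(p))
        metadata = read_metadata_tsv(config.metadata_path)
        full = read_counts_tsv(config.counts_path, metadata=metadata)
        taxonomy = (
            read_taxonomy_tsv(config.taxonomy_path) if config.taxonomy_path else None
        )
        for reactor in config.reactors:
            tables[reactor] = full.for_reactor(reactor)
            taxonomies[reactor] = taxonomy
        for series in read_activity_series(config.activity_path):
            activities[(series.reactor, series.enzyme)] = series
        _log("inputs", f"loaded {full.counts.shape[0]} samples × {full.counts.shape[1]} ASVs")

    # ---- stage: assay outputs ---------------------------------------------
    all_series = [activities[k] for k in sorted(activities)]
    _emit("activity.tsv", lambda p: write_activity_series(all_series, p))
    _log("assay", f"{len(all_series)} activity series written")

    # ---- stage: profile ----------------------------------------------------
    diversity_frames = []
    filtered: dict[str, AsvCountTable] = {}
    for reactor in config.reactors:
        ft = filter_samples(tables[reactor], config.min_reads)
        if ft.counts.empty:
            raise ConfigError(f"profile: no samples above {config.min_reads} reads in {reactor}")
        filtered[reactor] = ft
        diversity_frames.append(alpha_diversity_table(ft))
    diversity = pd.concat(diversity_frames)
    _emit("diversity.tsv", lambda p: diversity.rename_axis("sample").to_csv(p, sep="\t"))
    _log("profile", f"alpha diversity for {len(diversity)} samples")

    # ---- stage: ordination -------------------------------------------------
    summaries = []
    for reactor in config.reactors:
        ft = filtered[reactor]
        rel = to_relative(ft)
        rel = rel.loc[:, (rel > 0).any(axis=0)]
        ca = correspondence_analysis(rel)
        s = ordination_summary(ca)
        s.insert(0, "reactor", reactor)
        s.insert(1, "constraint", "")
        summaries.append(s)
        scores = ca.sample_scores.iloc[:, :2]
        _emit(f"ca_scores_{reactor}.tsv",
              lambda p, sc=scores: sc.rename_axis("sample").to_csv(p, sep="\t"))
        for enz in config.enzymes:
            act = activities[(reactor, enz)]
            day_to_rate = dict(zip((int(d) for d in act.days), act.rates))
            days = ft.metadata["day"].astype(int)
            usable = days.map(lambda d: d in day_to_rate)
            sub = ft.subset(usable)
            if sub.counts.shape[0] < 3:
                _log("ordinate", f"{reactor}/{enz}: <3 matched samples, RDA skipped")
                continue
            constraint = sub.metadata["day"].astype(int).map(day_to_rate).to_numpy()
            res = rda(
                sub.counts,
                constraint,
                n_permutations=config.n_permutations,
                transform=config.transform,
                seed=_stage_seed(config.seed or 0, f"rda:{reactor}:{enz}"),
            )
            s = ordination_summary(res)
            s.insert(0, "reactor", reactor)
            s.insert(1, "constraint", enz)
            summaries.append(s)
        _log("ordinate", f"{reactor}: CA + RDA complete")
    summary = pd.concat(summaries, ignore_index=True)
    _emit("ordination_summary.tsv", lambda p: summary.to_csv(p, sep="\t", index=False))

    # ---- stage: screen -----------------------------------------------------
    scfg = config.screen_config()
    n_tables = 0
    for reactor in config.reactors:
        for enz in config.enzymes:
            if (reactor, enz) not in activities:
                raise ConfigError(f"screen: no activity series for {reactor}/{enz}")
            ranking = screen(
                reactor, enz, tables[reactor], taxonomies[reactor],
                activities[(reactor, enz)], scfg,
            )
            _emit(f"candidates_{reactor}_{enz}.tsv", ranking.to_tsv)
            _log("screen", f"{reactor}/{enz}: {ranking.n_retained}/{ranking.n_screened} "
                           f"retained, top {len(ranking.table)} emitted")
            n_tables += 1
    manifest["n_candidate_tables"] = n_tables

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def simulate_and_evaluate(
    tracking_levels=(0.5, 0.7, 0.9, 1.0),
    n_seeds: int = 10,
    base_spec: CommunitySimSpec | None = None,
    screen_config: ScreenConfig | None = None,
    reactor: str = "R2",
    seed: int = 0,
    days: tuple[int, ...] | None = None,
) -> pd.DataFrame:
    """Recovery benchmark over a responder-tracking grid.

    For each tracking level and seed: plant responders, run the screen,
    and tabulate recovery (planted ∩ top-N / planted) and background
    intrusion ((top-N − planted) / N). Returns one row per run.
    """
    from hydroscreen.simulate import default_reactor_specs

    base_spec = base_spec or CommunitySimSpec(n_asvs=510, n_responders=10)
    screen_config = screen_config or ScreenConfig()
    profiles = default_reactor_specs()[reactor]
    if days is not None:
        profiles = {e: replace(s, days=tuple(days)) for e, s in profiles.items()}
    rows = []
    for tracking in tracking_levels:
        for i in range(n_seeds):
            run_seed = _stage_seed(seed, f"eval:{tracking}:{i}")
            spec = replace(base_spec, responder_tracking=tracking, seed=run_seed)
            series, table, taxonomy, truth = simulate_reactor(
                reactor, seed=run_seed, community_spec=spec,
                profile_specs=profiles,
            )
            try:
                ranking = screen(
                    reactor, "cellulase", table, taxonomy, series["cellulase"],
                    screen_config,
                )
            except ScreeningError as err:
                logger.warning("evaluate: screen failed at tracking=%s seed=%s: %s",
                               tracking, run_seed, err)
                continue
            top = set(ranking.table["asv_id"])
            planted = set(truth.responder_ids)
            recovered = len(top & planted)
            rows.append(
                {
                    "tracking": tracking,
                    "seed": run_seed,
                    "n_planted": len(planted),
                    "n_recovered": recovered,
                    "recovery": recovered / len(planted) if planted else np.nan,
                    "intrusion": (len(top) - recovered) / max(len(top), 1),
                    "n_retained": ranking.n_retained,
                }
            )
    return pd.DataFrame(rows)
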
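"""End-to-end orchestration over pairs x conditions x bands.

One pipeline run takes each dyad's raw (or simulated) dual recording plus
tap onsets through: downsample -> broadband artifact filter -> bad-channel
interpolation -> per-band zero-phase band-pass -> Hilbert phase -> wPLI /
PLV synchrony matrices -> surrogate-thresholded binary hyperbrain graph ->
topology metrics, and the tapping records through ITI / relative-phase /
SDRP summaries. The output is one tidy results row per
(pair, condition, band), deterministic under the configured seed.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as hio
from .behavior import TapRecord, summarize_behavior
from .connectivity import average_sync, compute_sync_matrices
from .graphmetrics import compute_graph_metrics
from .preprocessing import (
    BANDS,
    BROADBAND,
    DualRecording,
    bandpass,
    downsample,
    hilbert_phase,
    interpolate_bad_channels,
)
from .simulate import SimulationConfig, TapSimConfig, generate_coupled_pair, generate_tap_series
from .stats import paired_t_holm
from .surrogate import build_ensemble, significance_mask

logger = logging.getLogger("hyperbrain")

DEFAULT_CONDITIONS = ("slow", "fast", "free", "pseudo")


class ConfigError(ValueError):
    pass


@dataclass
class PairSpec:
    """Input sources for one dyad: files on disk or simulation parameters."""

    pair_id: str
    group: str = "stranger"
    #: condition -> (path_p1, path_p2) TSV recordings
    recordings: dict[str, tuple[str, str]] = field(default_factory=dict)
    #: condition -> tap CSV path
    tap_files: dict[str, str] = field(default_factory=dict)
    #: condition -> SimulationConfig, used when no recording file is given
    simulate: dict[str, SimulationConfig] = field(default_factory=dict)
    #: condition -> TapSimConfig, used when no tap file is given
    tap_sim: dict[str, TapSimConfig] = field(default_factory=dict)
    sampling_rate: float = 500.0
    bad_channels: tuple[tuple[str, ...], tuple[str, ...]] = ((), ())


@dataclass
class StudyConfig:
    """Everything one reproducible pipeline run needs."""

    pairs: list[PairSpec]
    bands: dict[str, tuple[float, float]] = field(default_factory=lambda: dict(BANDS))
    conditions: tuple[str, ...] = DEFAULT_CONDITIONS
    n_surrogates: int = 100
    alpha: float = 0.05
    target_rate: float = 250.0
    seed: int = 0
    #: fix the Bonferroni denominator at the full montage's 1653 regardless
    #: of exclusions; None recomputes it from actually tested pairs
    strict_n_tests: int | None = None
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must lie in (0, 1)")
        if len(set(self.conditions)) != len(self.conditions):
            raise ConfigError("condition names must be unique")
        if len(set(self.bands)) != len(self.bands):
            raise ConfigError("band names must be unique")


def load_study_config(path) -> StudyConfig:
    """Parse a YAML study config into a :class:`StudyConfig`."""
    raw = yaml.safe_load(Path(path).read_text())
    try:
        pairs = []
        for entry in raw["pairs"]:
            sim = {
                cond: SimulationConfig(**kw) for cond, kw in (entry.get("simulate") or {}).items()
            }
            tap_sim = {
                cond: TapSimConfig(**kw) for cond, kw in (entry.get("tap_sim") or {}).items()
            }
            recs = {
                cond: tuple(paths) for cond, paths in (entry.get("recordings") or {}).items()
            }
            bads = entry.get("bad_channels") or [[], []]
            pairs.append(
                PairSpec(
                    pair_id=str(entry["pair_id"]),
                    group=entry.get("group", "stranger"),
                    recordings=recs,
                    tap_files=entry.get("tap_files") or {},
                    simulate=sim,
                    tap_sim=tap_sim,
                    sampling_rate=float(entry.get("sampling_rate", 500.0)),
                    bad_channels=(tuple(bads[0]), tuple(bads[1])),
                )
            )
        bands = {
            name: (float(lo), float(hi))
            for name, (lo, hi) in (raw.get("bands") or BANDS).items()
        }
        return StudyConfig(
            pairs=pairs,
            bands=bands,
            conditions=tuple(raw.get("conditions", DEFAULT_CONDITIONS)),
            n_surrogates=int(raw.get("n_surrogates", 100)),
            alpha=float(raw.get("alpha", 0.05)),
            target_rate=float(raw.get("target_rate", 250.0)),
            seed=int(raw.get("seed", 0)),
            out_dir=raw.get("out_dir"),
        )
    except (KeyError, TypeError) as exc:
        raise ConfigError(f"malformed study config: {exc}") from exc


def _load_recording(pair: PairSpec, condition: str) -> DualRecording | None:
    if condition in pair.recordings:
        p1, p2 = pair.recordings[condition]
        rec = hio.read_recording_tsv(p1, p2, sampling_rate=pair.sampling_rate)
        return dataclasses.replace(rec, bad_channels=pair.bad_channels)
    if condition in pair.simulate:
        return generate_coupled_pair(pair.simulate[condition])
    return None


def _load_taps(pair: PairSpec, condition: str) -> tuple[TapRecord, TapRecord] | None:
    if condition in pair.tap_files:
        records = hio.read_taps_csv(pair.tap_files[condition])
        if len(records) != 2:
            raise ConfigError(
                f"tap file for {pair.pair_id}/{condition} must hold exactly 2 participants"
            )
        return records[0], records[1]
    if condition in pair.tap_sim:
        return generate_tap_series(pair.tap_sim[condition])
    return None


@dataclass
class PipelineResult:
    table: pd.DataFrame
    failures: list[tuple[str, str, str]]  # (pair_id, condition, message)


def run_pipeline(config: StudyConfig) -> PipelineResult:
    """Run every (pair, condition, band) cell and assemble the results table.

    Per-pair failures are logged and recorded; the run continues. Artifacts
    (sync matrices, graphs) are written under ``config.out_dir`` when set.
    """
    rows = []
    failures = []
    out_root = Path(config.out_dir) if config.out_dir else None
    for pair_idx, pair in enumerate(config.pairs):
        for cond_idx, condition in enumerate(config.conditions):
            try:
                rec = _load_recording(pair, condition)
                taps = _load_taps(pair, condition)
                if rec is None and taps is None:
                    continue
                behavior = None
                if taps is not None:
                    behavior = summarize_behavior(*taps)
                if rec is None:
                    continue
                logger.info("pair=%s condition=%s: preprocessing", pair.pair_id, condition)
                rec = downsample(rec, config.target_rate)
                rec = bandpass(rec, *BROADBAND)
                if any(pair.bad_channels):
                    rec = dataclasses.replace(rec, bad_channels=pair.bad_channels)
                    rec = interpolate_bad_channels(rec)
                for band_idx, (band, (lo, hi)) in enumerate(sorted(config.bands.items())):
                    narrow = bandpass(rec, lo, hi)
                    if narrow.band_tag is None:  # unnamed custom band
                        narrow = dataclasses.replace(narrow, band_tag=band)
                    phases = hilbert_phase(narrow)
                    sync = compute_sync_matrices(phases)
                    avg = average_sync(sync)
                    seed = np.random.SeedSequence(
                        (config.seed, pair_idx, cond_idx, band_idx)
                    ).generate_state(1)[0] % (2**31)
                    ens = build_ensemble(narrow, config.n_surrogates, seed=int(seed))
                    graph = significance_mask(
                        sync,
                        ens,
                        alpha=config.alpha,
                        condition=condition,
                        n_tests=config.strict_n_tests,
                    )
                    metrics = compute_graph_metrics(graph)
                    blocks = graph.block_edge_counts()
                    row = {
                        "pair_id": pair.pair_id,
                        "group": pair.group,
                        "condition": condition,
                        "band": band,
                        "mean_iti": behavior.mean_iti if behavior else np.nan,
                        "sdrp": behavior.sdrp if behavior else np.nan,
                        "resultant_length": behavior.resultant_length if behavior else np.nan,
                        "averaged_wpli_1": avg.averaged_wpli[0],
                        "averaged_wpli_2": avg.averaged_wpli[1],
                        "averaged_plv": avg.averaged_plv,
                        "edge_number": metrics.edge_number,
                        "edges_intra_1": blocks["intra_1"],
                        "edges_intra_2": blocks["intra_2"],
                        "edges_inter": blocks["inter"],
                        "global_efficiency": metrics.global_efficiency,
                        "local_efficiency": metrics.local_efficiency,
                        "modularity": metrics.modularity,
                        "char_path_length": metrics.char_path_length,
                        "clustering_coefficient": metrics.clustering_coefficient,
                        "n_samples_used": sync.n_samples_used,
                        "n_surrogates": config.n_surrogates,
                        "alpha_per_test": graph.alpha_per_test,
                        "surrogate_seed": int(seed),
                    }
                    rows.append(row)
                    if out_root is not None:
                        cell = out_root / pair.pair_id / condition / band
                        hio.write_sync_matrices(
                            sync, cell / "sync", {"condition": condition, "pair": pair.pair_id}
                        )
                        hio.write_graph(graph, cell / "graph")
            except Exception as exc:  # per-cell failure: record and continue
                logger.warning("pair=%s condition=%s failed: %s", pair.pair_id, condition, exc)
                failures.append((pair.pair_id, condition, str(exc)))
    table = pd.DataFrame(rows)
    if out_root is not None and not table.empty:
        out_root.mkdir(parents=True, exist_ok=True)
        table.to_csv(out_root / "results.tsv", sep="\t", index=False)
    return PipelineResult(table=table, failures=failures)


def condition_posthoc(table: pd.DataFrame, metric: str, band: str):
    """Paired t-tests (Holm-adjusted) of ``metric`` across conditions within a band.

    Subjects are pairs; each must have one value per condition in the band.
    """
    sub = table[table["band"] == band]
    wide = sub.pivot(index="pair_id", columns="condition", values=metric)
    return paired_t_holm(wide.to_numpy(), condition_names=list(wide.columns))
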
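"""End-to-end orchestration of the circuit-topology analysis pipeline.

The standard workflow: contacts -> lifetimes -> regime segmentation ->
regime-filtered topology trajectories (short and middle life; long-life
contacts are set aside) -> topology landscapes with evolution scores ->
representative topology strings -> string similarity.  All stage
parameters live in :class:`PipelineConfig`; every output carries the
config hash so a run is replayable from config + inputs alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import yaml

from .annotations import annotate_contacts, charged_contact_ratio, default_scales
from .contacts import (
    ContactTrajectory,
    LifetimeTable,
    compute_lifetimes,
    cumulative_contact_map,
    filter_by_regime,
)
from .landscape import TopologyLandscape, topology_trajectory
from .regimes import LifetimeRegimeModel
from .strings import align_similarity, coarse_grain, representative_string, write_topo

__all__ = ["PipelineConfig", "PipelineError", "run_full_pipeline"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass(frozen=True)
class PipelineConfig:
    """All stage parameters, with the standard defaults.

    Contact detection: 4.5 A heavy-atom cutoff, >= 1 atom pair, sequence
    separation >= 3.  Timescales: 5 ns frame interval, R^2 thresholds
    t1 = 0.8 and t2 = 0.3.  Clustering: k in 1..10, 100 initialisations,
    tolerance 1e-4, 10000 max iterations, covariance regularisation 1e-6.
    Strings: coarse-graining window 5 (S=0..X=4), global alignment with
    match/mismatch/gap = 1/0/0.
    """

    seed: int = 0
    distance_cutoff: float = 4.5
    min_atom_pairs: int = 1
    min_seq_separation: int = 3
    frame_interval: float = 5.0
    bandwidth: float | None = None
    t1: float = 0.8
    t2: float = 0.3
    k_min: int = 1
    k_max: int = 10
    n_init: int = 100
    tol: float = 1e-4
    max_iter: int = 10_000
    reg_covar: float = 1e-6
    bic_direction: str = "min"
    cg_window: int = 5
    alignment_method: str = "global"
    coarse: bool = True

    def __post_init__(self) -> None:
        if self.distance_cutoff <= 0 or self.frame_interval <= 0:
            raise ValueError("cutoff and frame interval must be positive")
        if not 0 < self.t2 < self.t1:
            raise ValueError("thresholds must satisfy 0 < t2 < t1")
        if not 1 <= self.k_min <= self.k_max:
            raise ValueError("need 1 <= k_min <= k_max")
        if self.bic_direction not in ("min", "max"):
            raise ValueError("bic_direction must be 'min' or 'max'")
        if self.alignment_method not in ("global", "blocks"):
            raise ValueError("alignment_method must be 'global' or 'blocks'")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @property
    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _stage(name: str):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as err:
            raise PipelineError(f"stage {name!r} failed: {err}") from err

    return wrap


def run_full_pipeline(
    config: PipelineConfig,
    trajectory: ContactTrajectory | str | Path,
    sequence: str | None = None,
    outdir: str | Path | None = None,
) -> dict:
    """Run the full analysis on a contact trajectory.

    Parameters
    ----------
    config
        Stage parameters; all randomness flows from ``config.seed``.
    trajectory
        A :class:`ContactTrajectory` or a path to a contact TSV.
    sequence
        Optional amino-acid sequence for biophysical annotation.
    outdir
        If given, results are written there (TSV/JSON/.topo) together
        with a ``run.json`` metadata block.

    Returns
    -------
    dict
        The result bundle: lifetime table, regime results, per-regime
        landscapes and evolution scores, representative strings,
        similarity score, annotation table, and metadata.
    """
    if isinstance(trajectory, (str, Path)):
        path = Path(trajectory)
        if not path.exists():
            raise PipelineError(f"stage 'load' failed: no such input file: {path}")
        trajectory = _stage("load")(
            ContactTrajectory.from_tsv, path, frame_interval=config.frame_interval
        )

    lifetimes = _stage("lifetimes")(compute_lifetimes, trajectory)
    regime_model = LifetimeRegimeModel(
        lifetimes,
        frame_interval=config.frame_interval,
        bandwidth=config.bandwidth,
        t1=config.t1,
        t2=config.t2,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        regime_results = _stage("regimes")(regime_model.fit)
    labeled = _stage("regimes")(regime_results.assign, lifetimes)

    landscapes: dict[str, object] = {}
    strings: dict[str, object] = {}
    for regime in ("short", "middle"):
        filtered = _stage(f"filter-{regime}")(
            filter_by_regime, trajectory, labeled, regime
        )
        coords = _stage(f"coords-{regime}")(topology_trajectory, filtered)
        try:
            res = TopologyLandscape(coords).fit(
                k_range=range(config.k_min, config.k_max + 1),
                n_init=config.n_init,
                tol=config.tol,
                max_iter=config.max_iter,
                reg_covar=config.reg_covar,
                seed=config.seed,
                bic_direction=config.bic_direction,
            )
        except Exception as err:
            raise PipelineError(f"stage 'landscape-{regime}' failed: {err}") from err
        landscapes[regime] = res
        try:
            s = representative_string(res, filtered)
            if config.coarse:
                s = coarse_grain(s, window=config.cg_window)
            strings[regime] = dataclasses.replace(
                s, source=(regime, "0", s.source[2] if s.source[2] else "")
            )
        except ValueError:
            strings[regime] = None  # too few contacts in the chosen frame

    similarity = None
    if strings.get("short") is not None and strings.get("middle") is not None:
        similarity = align_similarity(
            strings["short"], strings["middle"], method=config.alignment_method
        )

    annotation = None
    charged_ratios = None
    if sequence is not None:
        annotation = _stage("annotate")(annotate_contacts, labeled, sequence)
        by_regime = labeled.regime_of()
        short_set = [c for c, r in by_regime.items() if r == "short"]
        longer = [c for c, r in by_regime.items() if r in ("middle", "long")]
        charged_ratios = {
            "short": charged_contact_ratio(short_set, sequence) if short_set else None,
            "middle_long": charged_contact_ratio(longer, sequence) if longer else None,
        }

    bundle = {
        "config": config,
        "config_hash": config.hash,
        "trajectory": trajectory,
        "cumulative_contacts": cumulative_contact_map(trajectory),
        "lifetimes": labeled,
        "regimes": regime_results,
        "landscapes": landscapes,
        "evolution_scores": {k: v.evolution for k, v in landscapes.items()},
        "strings": strings,
        "similarity": similarity,
        "annotation": annotation,
        "charged_ratios": charged_ratios,
    }
    if outdir is not None:
        _write_bundle(bundle, Path(outdir))
    return bundle


def _write_bundle(bundle: dict, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    config: PipelineConfig = bundle["config"]
    meta = {"config": config.to_dict(), "config_hash": bundle["config_hash"]}

    bundle["lifetimes"].to_tsv(outdir / "lifetimes.tsv")
    regimes = bundle["regimes"].to_dict()
    regimes["config_hash"] = bundle["config_hash"]
    (outdir / "regimes.json").write_text(json.dumps(regimes, indent=2))

    for regime, res in bundle["landscapes"].items():
        d = res.to_dict()
        d["config_hash"] = bundle["config_hash"]
        (outdir / f"landscape_{regime}.json").write_text(json.dumps(d, indent=2))
        res.frame_table().to_csv(outdir / f"coords_{regime}.tsv", sep="\t", index=False)

    present = [s for s in bundle["strings"].values() if s is not None]
    if present:
        write_topo(outdir / "strings.topo", present)
    summary = dict(meta)
    summary["evolution_scores"] = bundle["evolution_scores"]
    summary["similarity_short_vs_middle"] = bundle["similarity"]
    if bundle["charged_ratios"] is not None:
        summary["charged_ratios"] = bundle["charged_ratios"]
    (outdir / "run.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    if bundle["annotation"] is not None:
        bundle["annotation"].to_csv(outdir / "annotated.tsv", sep="\t", index=False)
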
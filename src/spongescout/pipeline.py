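"""End-to-end orchestration: preprocess -> screen -> KCI -> target filter ->
prognostic -> downstream, per cohort, with reproducibility metadata."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from spongescout import __version__
from spongescout import correlation, downstream, kci, preprocess, prognostic
from spongescout import target_filter as tf
from spongescout.matrix import ExpressionMatrix

log = logging.getLogger("spongescout")


@dataclass
class RunConfig:
    expression_paths: dict[str, str] = field(default_factory=dict)  # subtype -> TSV
    survival_path: str | None = None
    target_paths: list[str] = field(default_factory=list)
    annotation_path: str | None = None
    output_dir: str = "spongescout_out"
    t: float = correlation.DEFAULT_SENSITIVITY_THRESHOLD
    rho_min: float = correlation.DEFAULT_RHO_MIN
    screen_p: float = correlation.DEFAULT_P_MAX
    kci_alpha: float = kci.DEFAULT_ALPHA
    kci_null_draws: int = 1000
    min_sources: int = 1
    proximity_window: int = downstream.DEFAULT_WINDOW
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.t < 2.0:
            raise ValueError("t must be in (0, 2)")
        for name in ("screen_p", "kci_alpha"):
            if not 0.0 < getattr(self, name) < 1.0:
                raise ValueError(f"{name} must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))


@dataclass
class RunReport:
    version: str = __version__
    seed: int = 0
    parameters: dict = field(default_factory=dict)
    counts: dict[str, dict[str, int]] = field(default_factory=dict)
    errors: dict[str, str] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts).T


STEPS = ("screen", "kci", "target_filter", "prognostic")


def run_subtype(
    subtype: str,
    matrix: ExpressionMatrix,
    cfg: RunConfig,
    survival: pd.DataFrame | None = None,
    targets: tf.TargetDatabase | None = None,
    locations: dict | None = None,
):
    """Run the full per-cohort chain; returns (counts, triplets, extras)."""
    counts: dict[str, int] = {}
    extras: dict = {}

    pre = preprocess.preprocess(matrix)
    candidates = correlation.screen_candidates(
        pre, t=cfg.t, rho_min=cfg.rho_min, p_max=cfg.screen_p
    )
    passing = [c for c in candidates if c.passes_threshold]
    counts["screen"] = len(passing)

    kcfg = kci.KernelConfig(
        n_null_draws=cfg.kci_null_draws, alpha=cfg.kci_alpha, seed=cfg.seed
    )
    confirmed = kci.confirm_triplets(passing, pre, kcfg)
    counts["kci"] = len(confirmed)

    if targets is not None:
        confirmed = tf.filter_by_support(confirmed, targets, cfg.min_sources)
    counts["target_filter"] = len(confirmed)

    if survival is not None and confirmed:
        trips = sorted({(t["lncrna"], t["mirna"], t["mrna"]) for t in confirmed})
        ranked = prognostic.rank_triplets(trips, pre.values, survival)
        extras["prognostic"] = ranked
        counts["prognostic"] = int(
            ranked.loc[ranked["verdict"] == "prognostic", ["lncrna", "mirna", "mrna"]]
            .drop_duplicates().shape[0]
        )
    else:
        counts["prognostic"] = 0

    if confirmed:
        extras["clusters"] = downstream.cluster_triplet_mrnas(confirmed, pre.values)
        if locations:
            confirmed = downstream.proximal_triplets(
                confirmed, locations, cfg.proximity_window
            )
        extras["network"] = downstream.export_network(confirmed)
    return counts, confirmed, extras


def run_all(cfg: RunConfig) -> RunReport:
    """Run every configured cohort and write result tables."""
    report = RunReport(seed=cfg.seed, parameters=asdict(cfg))
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    survival = None
    if cfg.survival_path:
        survival = pd.read_csv(cfg.survival_path, sep="\t").set_index("patient")
    targets = tf.load_targets(cfg.target_paths) if cfg.target_paths else None
    locations = (
        downstream.read_gtf(cfg.annotation_path) if cfg.annotation_path else None
    )

    triplet_sets: dict[str, set] = {}
    for subtype in sorted(cfg.expression_paths):
        path = cfg.expression_paths[subtype]
        try:
            matrix = ExpressionMatrix.from_tsv(path, subtype=subtype)
            counts, confirmed, extras = run_subtype(
                subtype, matrix, cfg, survival, targets, locations
            )
        except Exception as exc:  # keep other subtypes alive
            log.exception("subtype %s failed", subtype)
            report.errors[subtype] = f"{type(exc).__name__}: {exc}"
            continue
        report.counts[subtype] = counts
        triplet_sets[subtype] = {
            (t["lncrna"], t["mirna"], t["mrna"]) for t in confirmed
        }
        _write_outputs(outdir / subtype, confirmed, extras, cfg)

    if len(triplet_sets) > 1:
        _write_overlap(outdir / "subtype_overlap.tsv", triplet_sets)
    report.to_frame().to_csv(outdir / "step_counts.tsv", sep="\t")
    return report


def _write_outputs(subdir: Path, confirmed, extras, cfg: RunConfig) -> None:
    subdir.mkdir(parents=True, exist_ok=True)
    header = (
        f"# spongescout {__version__} t={cfg.t} rho_min={cfg.rho_min} "
        f"screen_p={cfg.screen_p} kci_alpha={cfg.kci_alpha} seed={cfg.seed}\n"
    )
    trip_path = subdir / "triplets.tsv"
    with open(trip_path, "w") as fh:
        fh.write(header)
        pd.DataFrame(confirmed).to_csv(fh, sep="\t", index=False)
    if "prognostic" in extras:
        with open(subdir / "prognostic.tsv", "w") as fh:
            fh.write(header)
            extras["prognostic"].to_csv(fh, sep="\t", index=False)
    if "clusters" in extras:
        rows = [
            {"lncrna": c.lncrna, "mirna": c.mirna,
             "cluster": c.cluster_index, "mrnas": ",".join(c.members)}
            for c in extras["clusters"]
        ]
        pd.DataFrame(rows).to_csv(subdir / "clusters.tsv", sep="\t", index=False)
    if "network" in extras:
        nodes, edges, lnc_tbl, mir_tbl = extras["network"]
        downstream.write_network_files(nodes, edges, subdir / "network")
        lnc_tbl.to_csv(subdir / "lncrna_sponge_counts.tsv", sep="\t", index=False)
        mir_tbl.to_csv(subdir / "mirna_sponge_counts.tsv", sep="\t", index=False)


def _write_overlap(path: Path, triplet_sets: dict[str, set]) -> None:
    all_triplets = sorted(set().union(*triplet_sets.values()))
    rows = []
    for trip in all_triplets:
        row = {"lncrna": trip[0], "mirna": trip[1], "mrna": trip[2]}
        for subtype, trips in sorted(triplet_sets.items()):
            row[subtype] = trip in trips
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
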
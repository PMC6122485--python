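"""Synthetic inputs with planted sponge structure and known ground truth.

Nothing here models real RNA-seq; the generator only reproduces the
statistical structure the discovery pipeline assumes: negatively
miRNA-coupled lncRNA/mRNA pairs that are conditionally independent given
the miRNA, confounded and independent null triplets, survival with a
pattern-dependent hazard, target databases with planted pairs plus decoys,
and gene coordinates with a controlled proximal fraction.

All expression is generated on the log2 scale and exponentiated to an
RPKM-like positive scale; the pipeline's log2 step recovers the linear
structure exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from spongescout.downstream import GenomicLocation, write_gtf
from spongescout.matrix import ExpressionMatrix
from spongescout.prognostic import SurvivalRecord
from spongescout.target_filter import TARGET_COLUMNS, TargetDatabase

LOG_MEAN_MIRNA = 4.0       # log2 RPKM center of miRNA expression
LOG_MEAN_TARGET = 10.0     # baseline intercept for lncRNA/mRNA
BASELINE_HAZARD = 0.01     # events per unit follow-up time


@dataclass
class SimulationConfig:
    n_samples: int = 200
    n_planted: int = 20
    n_null_confounded: int = 20
    n_null_independent: int = 20
    coupling_strength: float = 1.0
    noise_sd: float = 0.3
    hazard_ratio: float = 3.0
    censor_rate: float = 0.2
    decoy_rate: float = 0.0
    n_prognostic: int = 1
    proximal_fraction: float = 0.0
    balanced_pattern_hazard: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_samples", "n_planted", "n_null_confounded",
                     "n_null_independent"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.n_samples < 10:
            raise ValueError("n_samples < 10: downstream tests meaningless")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.hazard_ratio <= 0:
            raise ValueError("hazard_ratio must be > 0")
        if not 0.0 <= self.censor_rate < 1.0:
            raise ValueError("censor_rate must be in [0, 1)")
        if not 0.0 <= self.decoy_rate <= 1.0:
            raise ValueError("decoy_rate must be in [0, 1]")
        self.n_prognostic = min(self.n_prognostic, self.n_planted)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        import yaml

        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))


@dataclass
class GroundTruth:
    planted_triplets: list[tuple[str, str, str]] = field(default_factory=list)
    null_triplets: list[dict] = field(default_factory=list)
    prognostic_triplets: list[tuple[str, str, str]] = field(default_factory=list)
    proximal_planted: list[tuple[str, str, str]] = field(default_factory=list)
    coordinates: dict[str, GenomicLocation] = field(default_factory=dict)

    def all_rna_ids(self) -> list[str]:
        ids: list[str] = []
        for t in self.planted_triplets:
            ids.extend(t)
        for rec in self.null_triplets:
            ids.extend(rec["triplet"])
        return ids

    def to_json(self, path) -> None:
        payload = {
            "planted_triplets": [list(t) for t in self.planted_triplets],
            "null_triplets": [
                {"triplet": list(r["triplet"]), "kind": r["kind"]}
                for r in self.null_triplets
            ],
            "prognostic_triplets": [list(t) for t in self.prognostic_triplets],
            "proximal_planted": [list(t) for t in self.proximal_planted],
            "coordinates": {
                rid: asdict(loc) for rid, loc in self.coordinates.items()
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            planted_triplets=[tuple(t) for t in payload["planted_triplets"]],
            null_triplets=[
                {"triplet": tuple(r["triplet"]), "kind": r["kind"]}
                for r in payload["null_triplets"]
            ],
            prognostic_triplets=[
                tuple(t) for t in payload["prognostic_triplets"]
            ],
            proximal_planted=[tuple(t) for t in payload["proximal_planted"]],
            coordinates={
                rid: GenomicLocation(**loc)
                for rid, loc in payload["coordinates"].items()
            },
        )


def _triplet_ids(prefix: str, idx: int) -> tuple[str, str, str]:
    return (f"LNC-{prefix}{idx:04d}", f"MIR-{prefix}{idx:04d}",
            f"GEN-{prefix}{idx:04d}")


def simulate_expression(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, GroundTruth]:
    """Expression matrix with planted sponge triplets plus two null classes.

    Planted triplet (X=lncRNA, Y=mRNA, Z=miRNA), on the log2 scale:
    Z ~ N(mu, 1), X = a - b Z + eps, Y = a - b Z + eps' with
    b = coupling_strength and independent N(0, noise_sd) noise, so X and Y
    are positively correlated, each negatively correlated with Z, and
    conditionally independent given Z.  Confounded nulls add a direct
    X -> Y term of the same strength, breaking conditional independence.
    Independent nulls are mutually independent.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    b = config.coupling_strength
    sd = config.noise_sd
    samples = [f"S{i:04d}" for i in range(n)]

    truth = GroundTruth()
    rows: list[np.ndarray] = []
    ids: list[str] = []
    classes: list[str] = []

    def add_trio(trio, x, z, y):
        lnc, mir, mrna = trio
        rows.extend([x, z, y])
        ids.extend([lnc, mir, mrna])
        classes.extend(["lncRNA", "miRNA", "mRNA"])

    for i in range(config.n_planted):
        trio = _triplet_ids("P", i)
        z = rng.normal(LOG_MEAN_MIRNA, 1.0, n)
        x = LOG_MEAN_TARGET - b * z + rng.normal(0.0, sd, n)
        y = LOG_MEAN_TARGET - b * z + rng.normal(0.0, sd, n)
        add_trio(trio, x, z, y)
        truth.planted_triplets.append(trio)

    for i in range(config.n_null_confounded):
        trio = _triplet_ids("C", i)
        z = rng.normal(LOG_MEAN_MIRNA, 1.0, n)
        x = LOG_MEAN_TARGET - b * z + rng.normal(0.0, sd, n)
        y = LOG_MEAN_TARGET - b * z + b * (x - x.mean()) \
            + rng.normal(0.0, sd, n)
        add_trio(trio, x, z, y)
        truth.null_triplets.append({"triplet": trio, "kind": "confounded"})

    for i in range(config.n_null_independent):
        trio = _triplet_ids("I", i)
        z = rng.normal(LOG_MEAN_MIRNA, 1.0, n)
        x = rng.normal(LOG_MEAN_TARGET - b * LOG_MEAN_MIRNA, 1.0, n)
        y = rng.normal(LOG_MEAN_TARGET - b * LOG_MEAN_MIRNA, 1.0, n)
        add_trio(trio, x, z, y)
        truth.null_triplets.append({"triplet": trio, "kind": "independent"})

    truth.prognostic_triplets = truth.planted_triplets[: config.n_prognostic]

    values = pd.DataFrame(
        np.exp2(np.vstack(rows)), index=ids, columns=samples
    )
    matrix = ExpressionMatrix(
        values=values,
        rna_class=pd.Series(classes, index=ids),
        subtype="synthetic",
        log_scale=False,
    )
    return matrix, truth


def _pattern_cells(log_expr: pd.DataFrame, trio, balanced: bool) -> np.ndarray:
    """Patients in the up-down-up cell by per-RNA medians.

    With ``balanced`` the mirrored down-up-down cell is included too,
    which keeps every single-RNA median split exactly null in expectation
    while the 3-way pattern carries the full effect (the mirrored pair is
    the unique two-cell choice with that property).
    """
    lnc, mir, mrna = trio
    lnc_up = log_expr.loc[lnc] > log_expr.loc[lnc].median()
    mir_up = log_expr.loc[mir] > log_expr.loc[mir].median()
    mrna_up = log_expr.loc[mrna] > log_expr.loc[mrna].median()
    cells = lnc_up & ~mir_up & mrna_up
    if balanced:
        cells = cells | (~lnc_up & mir_up & ~mrna_up)
    return cells.to_numpy()


def _draw_survival(
    rng: np.random.Generator,
    hazard_mult: np.ndarray,
    censor_rate: float,
    patients,
) -> list[SurvivalRecord]:
    """Exponential times at BASELINE_HAZARD x mult; Bernoulli censoring
    with the censoring time uniform inside the event time."""
    times = rng.exponential(1.0 / (BASELINE_HAZARD * hazard_mult))
    censored = rng.random(times.size) < censor_rate
    u = rng.random(times.size)
    return [
        SurvivalRecord(p, float(t * u_i), 0) if c
        else SurvivalRecord(p, float(t), 1)
        for p, t, c, u_i in zip(patients, times, censored, u)
    ]


def simulate_survival(
    expr: ExpressionMatrix,
    truth: GroundTruth,
    config: SimulationConfig,
) -> list[SurvivalRecord]:
    """Survival whose hazard depends on triplet expression patterns.

    Patients inside the up-down-up cell (both mirrored cells when
    ``balanced_pattern_hazard`` is set) of any prognostic planted triplet
    get their hazard multiplied by ``hazard_ratio``.
    """
    rng = np.random.default_rng(config.seed + 1)
    log_expr = np.log2(expr.values) if not expr.log_scale else expr.values
    mult = np.ones(expr.n_samples)
    for trio in truth.prognostic_triplets:
        in_cell = _pattern_cells(log_expr, trio,
                                 config.balanced_pattern_hazard)
        mult = mult * np.where(in_cell, config.hazard_ratio, 1.0)
    return _draw_survival(rng, mult, config.censor_rate, expr.sample_ids)


def simulate_prognostic_cohort(
    n_samples: int = 400,
    hazard_ratio: float = 3.0,
    censor_rate: float = 0.2,
    seed: int = 0,
    low: float = 0.0,
    high: float = 2.0,
) -> tuple[pd.DataFrame, pd.DataFrame, tuple[str, str, str]]:
    """Two-level expression cohort for calibrating the prognostic stage.

    Each RNA of one triplet is an independent fair coin between two exact
    expression levels, so every valid candidate cutoff collapses onto the
    same (cluster) split: cutoff selection is deterministic and the
    single-RNA log-rank tests are exactly the median-split test.  The
    hazard is planted on the mirrored up-down-up / down-up-down cells,
    leaving all three single-RNA splits null by construction.

    Returns (expression RNAs x patients, survival frame, triplet ids).
    """
    rng = np.random.default_rng(seed)
    patients = [f"P{i:04d}" for i in range(n_samples)]
    trio = ("LNC-SURV", "MIR-SURV", "GEN-SURV")
    levels = {}
    up = {}
    for rna in trio:
        coin = rng.random(n_samples) < 0.5
        up[rna] = coin
        levels[rna] = np.where(coin, high, low)
    expr = pd.DataFrame(levels, index=patients).T
    lnc, mir, mrna = trio
    cell = (up[lnc] & ~up[mir] & up[mrna]) | (~up[lnc] & up[mir] & ~up[mrna])
    mult = np.where(cell, hazard_ratio, 1.0)
    records = _draw_survival(rng, mult, censor_rate, patients)
    surv = pd.DataFrame(
        {"time": [r.time for r in records],
         "event": [r.event for r in records]},
        index=patients,
    )
    return expr, surv, trio


def simulate_target_db(
    truth: GroundTruth, decoy_rate: float = 0.0, seed: int = 0
) -> TargetDatabase:
    """Planted (miRNA, lncRNA) and (miRNA, mRNA) pairs plus random decoys.

    Every planted pair appears with two sources (one predicted, one
    experimental).  Decoys are drawn Bernoulli(decoy_rate) over all
    non-planted (miRNA, target) combinations and never coincide with
    planted pairs.
    """
    rng = np.random.default_rng(seed)
    rows = []
    planted_pairs: set[tuple[str, str]] = set()
    for lnc, mir, mrna in truth.planted_triplets:
        for target, tclass in ((lnc, "lncRNA"), (mrna, "mRNA")):
            planted_pairs.add((mir, target))
            rows.append((mir, target, tclass, "SimPredictDB", "P"))
            rows.append((mir, target, tclass, "SimValidatedDB", "E"))

    if decoy_rate > 0:
        mirnas = sorted({t[1] for t in truth.planted_triplets}
                        | {r["triplet"][1] for r in truth.null_triplets})
        targets = sorted(
            {(t[0], "lncRNA") for t in truth.planted_triplets}
            | {(t[2], "mRNA") for t in truth.planted_triplets}
            | {(r["triplet"][0], "lncRNA") for r in truth.null_triplets}
            | {(r["triplet"][2], "mRNA") for r in truth.null_triplets}
        )
        for mir in mirnas:
            for target, tclass in targets:
                if (mir, target) in planted_pairs:
                    continue
                if rng.random() < decoy_rate:
                    rows.append((mir, target, tclass, "SimDecoyDB", "P"))

    pairs = pd.DataFrame(rows, columns=list(TARGET_COLUMNS))
    return TargetDatabase(pairs=pairs)


def simulate_annotation(
    truth: GroundTruth, proximal_fraction: float = 0.0, seed: int = 0
) -> list[GenomicLocation]:
    """Gene coordinates with a controlled fraction of proximal triplets.

    For ``round(proximal_fraction * n_planted)`` planted triplets the
    lncRNA and mRNA are placed within 100 kb on the same chromosome (the
    miRNA elsewhere); all other RNAs are spaced megabases apart so no
    accidental proximity arises.  The proximal triplets are recorded in
    ``truth.proximal_planted``.
    """
    rng = np.random.default_rng(seed)
    gene_len = 2_000
    spacing = 10_000_000
    n_chroms = 23
    locations: list[GenomicLocation] = []
    truth.proximal_planted = []

    n_proximal = int(round(proximal_fraction * len(truth.planted_triplets)))
    cursor = [1] * (n_chroms + 1)   # next free bp per chromosome

    def place(rna_id: str, chrom: int, start: int) -> GenomicLocation:
        loc = GenomicLocation(rna_id, f"chr{chrom}", start,
                              start + gene_len - 1, "+")
        locations.append(loc)
        truth.coordinates[rna_id] = loc
        return loc

    def place_spaced(rna_id: str) -> None:
        chrom = int(rng.integers(1, n_chroms + 1))
        place(rna_id, chrom, cursor[chrom])
        cursor[chrom] += spacing

    for i, trio in enumerate(truth.planted_triplets):
        lnc, mir, mrna = trio
        if i < n_proximal:
            chrom = int(rng.integers(1, n_chroms + 1))
            start = cursor[chrom]
            place(lnc, chrom, start)
            gap = int(rng.integers(0, 100_000 - gene_len))
            place(mrna, chrom, start + gene_len + gap)
            cursor[chrom] += spacing
            place_spaced(mir)
            truth.proximal_planted.append(trio)
        else:
            for rid in trio:
                place_spaced(rid)

    for rec in truth.null_triplets:
        for rid in rec["triplet"]:
            place_spaced(rid)
    return locations


def simulate_all(config: SimulationConfig):
    """Run every generator consistently from one config."""
    expr, truth = simulate_expression(config)
    survival = simulate_survival(expr, truth, config)
    targets = simulate_target_db(truth, config.decoy_rate, config.seed + 2)
    annotation = simulate_annotation(truth, config.proximal_fraction,
                                     config.seed + 3)
    return expr, truth, survival, targets, annotation


def write_dataset(config: SimulationConfig, outdir) -> dict[str, Path]:
    """Write all synthetic inputs into a directory; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    expr, truth, survival, targets, annotation = simulate_all(config)

    paths = {
        "expression": outdir / "expression.tsv",
        "survival": outdir / "survival.tsv",
        "targets": outdir / "targets.tsv",
        "annotation": outdir / "annotation.gtf",
        "truth": outdir / "truth.json",
    }
    expr.to_tsv(paths["expression"])
    pd.DataFrame(
        [{"patient": r.patient, "time": r.time, "event": r.event}
         for r in survival]
    ).to_csv(paths["survival"], sep="\t", index=False)
    targets.pairs.to_csv(paths["targets"], sep="\t", index=False)
    write_gtf(annotation, paths["annotation"])
    truth.to_json(paths["truth"])
    return paths
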
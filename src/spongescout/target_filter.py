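"""miRNA-target support filtering.

A candidate triplet survives only if the target database records the miRNA
targeting both the lncRNA and the mRNA.  Source provenance and per-side
database counts are kept for prioritization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

TARGET_COLUMNS = ("mirna", "target", "target_class", "source", "evidence")
VALID_TARGET_CLASSES = {"lncRNA", "mRNA"}
VALID_EVIDENCE = {"P", "E"}


class MalformedTargetFileError(ValueError):
    pass


@dataclass
class TargetDatabase:
    """Union of (mirna, target, target_class, source, evidence) rows."""

    pairs: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(TARGET_COLUMNS) - set(self.pairs.columns)
        if missing:
            raise ValueError(f"target table missing columns: {sorted(missing)}")
        dup = self.pairs.duplicated(subset=["mirna", "target", "source"])
        if dup.any():
            self.pairs = self.pairs.loc[~dup].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.pairs)

    def sources_for(self, mirna: str, target: str) -> list[str]:
        sel = self.pairs[
            (self.pairs["mirna"] == mirna) & (self.pairs["target"] == target)
        ]
        return sorted(sel["source"].unique())


def load_targets(files) -> TargetDatabase:
    """Union of target TSVs; duplicate pairs from different sources kept."""
    frames = []
    for path in files:
        df = pd.read_csv(path, sep="\t", dtype=str)
        missing = set(TARGET_COLUMNS) - set(df.columns)
        if missing:
            raise MalformedTargetFileError(
                f"{path}: missing columns {sorted(missing)}"
            )
        bad_rows = df[list(TARGET_COLUMNS[:4])].isna().any(axis=1)
        if bad_rows.any():
            line = int(bad_rows.idxmax()) + 2  # header + 1-based
            raise MalformedTargetFileError(f"{path}: malformed row at line {line}")
        bad_class = ~df["target_class"].isin(VALID_TARGET_CLASSES)
        if bad_class.any():
            line = int(bad_class.idxmax()) + 2
            raise MalformedTargetFileError(
                f"{path}: unknown target_class at line {line}"
            )
        frames.append(df[list(TARGET_COLUMNS)])
    if not frames:
        return TargetDatabase(pairs=pd.DataFrame(columns=list(TARGET_COLUMNS)))
    return TargetDatabase(pairs=pd.concat(frames, ignore_index=True))


def filter_by_support(
    triplets: list[dict], db: TargetDatabase, min_sources: int = 1
) -> list[dict]:
    """Keep triplets whose miRNA targets both partners in the database.

    Identifier matching is exact (no -5p/-3p stripping; arm identity
    matters).  ``min_sources`` raises the evidence bar per side.
    """
    by_pair: dict[tuple[str, str], list[str]] = {}
    for _, row in db.pairs.iterrows():
        by_pair.setdefault((row["mirna"], row["target"]), []).append(row["source"])

    kept = []
    for t in triplets:
        lnc_src = sorted(by_pair.get((t["mirna"], t["lncrna"]), []))
        mrna_src = sorted(by_pair.get((t["mirna"], t["mrna"]), []))
        if len(lnc_src) >= min_sources and len(mrna_src) >= min_sources:
            out = dict(t)
            out["lnc_support"] = ",".join(lnc_src)
            out["mrna_support"] = ",".join(mrna_src)
            out["n_support_lnc"] = len(lnc_src)
            out["n_support_mrna"] = len(mrna_src)
            kept.append(out)
    return kept
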
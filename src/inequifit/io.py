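"""Validated CSV/TSV input and output for the pipeline stages.

All files are UTF-8, comma-separated with a header row; money is stored in
integer JPY (the kJPY rescaling is internal to the likelihood).  Readers
raise :class:`~inequifit.errors.DataError` with row numbers (0-based data
rows) for anything off-schema, so CLI messages can point at the offending
lines.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import DataError
from .games import DecisionContext
from .preferences import CompiledSchedule

BEHAVIOUR_COLUMNS = ("participant_id", "game", "context_param", "chosen_label")
GENOTYPE_COLUMNS = (
    "participant_id",
    "oxtr",
    "avpr1a_allele1_bp",
    "avpr1a_allele2_bp",
    "oprm1",
    "age",
    "sex",
)

_SNP_LEVELS = {"AA", "AG", "GG"}
_SEX_LEVELS = {"female", "male"}


def _require_columns(frame: pd.DataFrame, columns: Sequence[str], what: str) -> None:
    missing = [c for c in columns if c not in frame.columns]
    if missing:
        raise DataError(f"{what} is missing required columns: {missing}")


def read_behaviour(
    path: Path, contexts: Optional[Sequence[DecisionContext]] = None
) -> pd.DataFrame:
    """Load a behaviour table; with ``contexts`` also validate every row
    against the schedule (known context, chosen label on the game's grid)."""
    frame = pd.read_csv(path)
    _require_columns(frame, BEHAVIOUR_COLUMNS, f"behaviour table {path}")
    if frame["participant_id"].isna().any() or frame["chosen_label"].isna().any():
        bad = frame.index[
            frame["participant_id"].isna() | frame["chosen_label"].isna()
        ].tolist()
        raise DataError(f"behaviour table {path}: missing values in rows {bad}", bad)
    if contexts is not None:
        compiled = CompiledSchedule(contexts)
        bad = []
        for i, row in enumerate(frame.itertuples()):
            key = (str(row.game), round(float(row.context_param), 6))
            label = row.chosen_label
            try:
                label = int(float(label))
            except (TypeError, ValueError):
                label = str(label)
            if (key, label) not in compiled._flat_index:
                bad.append(i)
        if bad:
            raise DataError(
                f"behaviour table {path}: rows {bad[:20]}"
                f"{'...' if len(bad) > 20 else ''} reference unknown contexts "
                "or off-grid choices",
                bad,
            )
    return frame


def read_genotypes(path: Path) -> pd.DataFrame:
    """Load and validate a genotype table; derived RS3 columns are appended."""
    frame = pd.read_csv(path)
    _require_columns(frame, GENOTYPE_COLUMNS, f"genotype table {path}")
    bad_rows: dict[int, str] = {}
    for i, row in enumerate(frame.itertuples()):
        if str(row.oxtr) not in _SNP_LEVELS or str(row.oprm1) not in _SNP_LEVELS:
            bad_rows[i] = "genotype not in {AA, AG, GG}"
        elif not (
            float(row.avpr1a_allele1_bp) > 0 and float(row.avpr1a_allele2_bp) > 0
        ):
            bad_rows[i] = "non-positive allele length"
        elif not float(row.age) > 0:
            bad_rows[i] = "non-positive age"
        elif str(row.sex) not in _SEX_LEVELS:
            bad_rows[i] = "sex not in {female, male}"
    if bad_rows:
        items = "; ".join(f"row {i}: {msg}" for i, msg in list(bad_rows.items())[:10])
        raise DataError(
            f"genotype table {path}: {len(bad_rows)} invalid rows ({items}"
            f"{'; ...' if len(bad_rows) > 10 else ''})",
            bad_rows,
        )
    from .genetics import add_derived_genotypes

    return add_derived_genotypes(frame)


def read_estimates(path: Path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    _require_columns(
        frame,
        ("participant_id", "alpha_mean", "beta_mean"),
        f"estimates table {path}",
    )
    return frame


def write_table(frame: pd.DataFrame, path: Path, sep: str = ",") -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False, sep=sep)
    return path
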
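"""Questionnaire definitions, respondent data I/O, completeness filtering and scoring.

The built-in instrument is the IKDC Subjective Knee Form: 19 items, of which
18 are scored (item 10a, knee function *prior* to injury, is collected but
never enters the score). Response codes are stored 0-based, ascending from
worst to best; the total score is a linear 0-100 transform of the summed
scored codes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import EmptyResultError, SchemaError, ValidationError

__all__ = [
    "ItemSpec",
    "InstrumentSpec",
    "ResponseMatrix",
    "CompletenessSummary",
    "builtin_ikdc",
    "read_responses",
    "write_responses",
    "complete_case_filter",
    "total_score",
]


@dataclass(frozen=True)
class ItemSpec:
    """One questionnaire item: an ordered categorical response scale."""

    item_id: str
    description: str
    n_categories: int
    scored: bool = True

    def __post_init__(self) -> None:
        if self.n_categories < 2:
            raise ValidationError(
                f"item {self.item_id!r}: n_categories must be >= 2, got {self.n_categories}"
            )


@dataclass(frozen=True)
class InstrumentSpec:
    """An ordered collection of items plus the raw-score bounds used by the
    0-100 transform.  ``min_raw``/``max_raw`` refer to the sum of 0-based
    codes over *scored* items."""

    name: str
    items: tuple[ItemSpec, ...]
    min_raw: int = 0
    max_raw: int = field(default=-1)

    def __post_init__(self) -> None:
        ids = [it.item_id for it in self.items]
        if len(set(ids)) != len(ids):
            raise ValidationError(f"duplicate item ids in instrument {self.name!r}")
        if self.max_raw < 0:
            object.__setattr__(
                self,
                "max_raw",
                self.min_raw + sum(it.n_categories - 1 for it in self.items if it.scored),
            )
        if self.max_raw <= self.min_raw:
            raise ValidationError("max_raw must exceed min_raw")

    @property
    def item_ids(self) -> list[str]:
        return [it.item_id for it in self.items]

    @property
    def scored_item_ids(self) -> list[str]:
        return [it.item_id for it in self.items if it.scored]

    def item(self, item_id: str) -> ItemSpec:
        for it in self.items:
            if it.item_id == item_id:
                return it
        raise KeyError(item_id)

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "min_raw": self.min_raw,
            "max_raw": self.max_raw,
            "items": [
                {
                    "item_id": it.item_id,
                    "description": it.description,
                    "n_categories": it.n_categories,
                    "scored": it.scored,
                }
                for it in self.items
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "InstrumentSpec":
        return cls(
            name=d["name"],
            items=tuple(
                ItemSpec(
                    item_id=i["item_id"],
                    description=i.get("description", ""),
                    n_categories=int(i["n_categories"]),
                    scored=bool(i.get("scored", True)),
                )
                for i in d["items"]
            ),
            min_raw=int(d.get("min_raw", 0)),
            max_raw=int(d.get("max_raw", -1)),
        )

    def save(self, path: str | Path) -> None:
        path = Path(path)
        text = (
            json.dumps(self.to_dict(), indent=2)
            if path.suffix == ".json"
            else yaml.safe_dump(self.to_dict(), sort_keys=False)
        )
        path.write_text(text)

    @classmethod
    def load(cls, path: str | Path) -> "InstrumentSpec":
        path = Path(path)
        raw = path.read_text()
        d = json.loads(raw) if path.suffix == ".json" else yaml.safe_load(raw)
        return cls.from_dict(d)


# The 19 IKDC items in questionnaire order with their response-option counts.
_IKDC_ITEMS: list[tuple[str, str, int, bool]] = [
    ("1", "Activity level without pain", 5, True),
    ("2", "Frequency of pain", 11, True),
    ("3", "Severity of pain", 11, True),
    ("4", "Stiffness/swelling", 5, True),
    ("5", "Activity level without swelling", 5, True),
    ("6", "Locking or catching", 2, True),
    ("7", "Activity level without giving way", 5, True),
    ("8", "Activity level on regular basis", 5, True),
    ("9a", "Ascending stairs", 5, True),
    ("9b", "Descending stairs", 5, True),
    ("9c", "Kneeling", 5, True),
    ("9d", "Squatting", 5, True),
    ("9e", "Sitting", 5, True),
    ("9f", "Rising from chair", 5, True),
    ("9g", "Running straight ahead", 5, True),
    ("9h", "Jumping/landing on involved leg", 5, True),
    ("9i", "Stopping and starting quickly", 5, True),
    ("10a", "Knee function prior to injury (not included in score)", 11, False),
    ("10b", "Current knee function", 11, True),
]


def builtin_ikdc() -> InstrumentSpec:
    """The IKDC Subjective Knee Form: 19 items, 18 scored (10a excluded)."""
    return InstrumentSpec(
        name="IKDC Subjective Knee Form",
        items=tuple(ItemSpec(*row) for row in _IKDC_ITEMS),
    )


@dataclass
class ResponseMatrix:
    """N x p integer response codes with an explicit missingness mask.

    ``values`` holds 0-based category codes (entries under the mask are
    arbitrary, conventionally 0). Columns follow ``item_ids``.
    """

    values: np.ndarray
    missing_mask: np.ndarray
    item_ids: list[str]
    respondent_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int64)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if self.values.shape != self.missing_mask.shape:
            raise ValidationError("values and missing_mask shapes differ")
        if self.values.shape != (len(self.respondent_ids), len(self.item_ids)):
            raise ValidationError("shape does not match respondent/item id lists")
        if self.n < 1:
            raise ValidationError("a ResponseMatrix needs at least one respondent")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    def column(self, item_id: str) -> int:
        try:
            return self.item_ids.index(item_id)
        except ValueError:
            raise KeyError(item_id) from None

    def subset_items(self, item_ids: Sequence[str]) -> "ResponseMatrix":
        cols = [self.column(i) for i in item_ids]
        return ResponseMatrix(
            values=self.values[:, cols].copy(),
            missing_mask=self.missing_mask[:, cols].copy(),
            item_ids=list(item_ids),
            respondent_ids=list(self.respondent_ids),
        )

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.item_ids, dtype="Int64")
        df = df.mask(pd.DataFrame(self.missing_mask, columns=self.item_ids))
        df.insert(0, "respondent_id", self.respondent_ids)
        return df


def _validate_codes(
    values: np.ndarray, mask: np.ndarray, item_ids: list[str], instrument: InstrumentSpec
) -> None:
    for j, item_id in enumerate(item_ids):
        spec = instrument.item(item_id)
        col = values[:, j]
        bad = (~mask[:, j]) & ((col < 0) | (col >= spec.n_categories))
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ValidationError(
                f"row {row}, item {item_id!r}: code {col[row]} outside "
                f"[0, {spec.n_categories - 1}]"
            )


def read_responses(
    path: str | Path,
    instrument: InstrumentSpec,
    *,
    one_based: bool = False,
    id_column: str = "respondent_id",
) -> ResponseMatrix:
    """Read a respondent CSV (header = item ids, blank cells = missing).

    Columns are reordered into instrument order; every scored item must be
    present, unknown columns raise :class:`SchemaError`.  ``one_based``
    accepts files coded 1..C instead of 0..C-1.
    """
    df = pd.read_csv(path, dtype="string")
    if id_column in df.columns:
        respondent_ids = df[id_column].astype(str).tolist()
        df = df.drop(columns=[id_column])
    else:
        respondent_ids = [str(i) for i in range(len(df))]

    known = set(instrument.item_ids)
    unknown = [c for c in df.columns if c not in known]
    if unknown:
        raise SchemaError(f"unknown column(s) {unknown!r} for instrument {instrument.name!r}")
    missing_cols = [c for c in instrument.scored_item_ids if c not in df.columns]
    if missing_cols:
        raise SchemaError(f"missing scored item column(s) {missing_cols!r}")
    if len(df) == 0:
        raise SchemaError("response file contains no respondent rows")

    ordered = [c for c in instrument.item_ids if c in df.columns]
    df = df[ordered]
    mask = df.isna().to_numpy()
    numeric = df.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    unparsable = np.isnan(numeric) & ~mask
    if unparsable.any():
        r, c = map(int, np.argwhere(unparsable)[0])
        raise ValidationError(f"row {r}, item {ordered[c]!r}: non-numeric cell")
    values = np.where(mask, 0.0, numeric)
    if not np.allclose(values, np.round(values)):
        raise ValidationError("response codes must be integers")
    values = np.round(values).astype(np.int64)
    if one_based:
        values = np.where(mask, 0, values - 1)
    _validate_codes(values, mask, ordered, instrument)
    return ResponseMatrix(values, mask, ordered, respondent_ids)


def write_responses(data: ResponseMatrix, path: str | Path) -> None:
    """Write codes as CSV in the same dialect ``read_responses`` accepts."""
    data.to_dataframe().to_csv(path, index=False)


@dataclass(frozen=True)
class CompletenessSummary:
    n_total: int
    n_complete: int

    @property
    def pct_complete(self) -> float:
        return 100.0 * self.n_complete / self.n_total

    @property
    def pct_complete_rounded(self) -> int:
        """Percentage of complete rows to the nearest whole percent."""
        return int(round(self.pct_complete))


def complete_case_filter(
    data: ResponseMatrix, instrument: InstrumentSpec | None = None
) -> tuple[ResponseMatrix, CompletenessSummary]:
    """Keep rows with no missing *scored* item; report completion counts."""
    if instrument is None:
        scored_cols = list(range(data.p))
    else:
        scored = set(instrument.scored_item_ids)
        scored_cols = [j for j, i in enumerate(data.item_ids) if i in scored]
    keep = ~data.missing_mask[:, scored_cols].any(axis=1)
    summary = CompletenessSummary(n_total=data.n, n_complete=int(keep.sum()))
    if summary.n_complete == 0:
        raise EmptyResultError("no complete rows after filtering")
    filtered = ResponseMatrix(
        values=data.values[keep],
        missing_mask=data.missing_mask[keep],
        item_ids=list(data.item_ids),
        respondent_ids=[r for r, k in zip(data.respondent_ids, keep) if k],
    )
    return filtered, summary


def total_score(
    data: ResponseMatrix,
    instrument: InstrumentSpec,
    *,
    allow_partial: bool = False,
    min_answered: int = 16,
) -> np.ndarray:
    """Per-respondent 0-100 total score (worst to best).

    score = 100 * (raw - min_raw) / (max_raw - min_raw), raw being the sum of
    0-based codes over scored items. Rows with missing scored items yield NaN
    unless ``allow_partial`` is set, in which case rows with at least
    ``min_answered`` scored answers are scored by mean substitution of the
    missing items (the official IKDC convention); sparser rows stay NaN.
    """
    scored_ids = [i for i in instrument.scored_item_ids if i in data.item_ids]
    missing_cols = [i for i in instrument.scored_item_ids if i not in data.item_ids]
    if missing_cols:
        raise SchemaError(f"data lacks scored item column(s) {missing_cols!r}")
    cols = [data.column(i) for i in scored_ids]
    vals = data.values[:, cols].astype(float)
    miss = data.missing_mask[:, cols]
    vals[miss] = np.nan

    n_items = len(cols)
    answered = n_items - miss.sum(axis=1)
    raw = np.nansum(vals, axis=1)
    with np.errstate(invalid="ignore"):
        raw_imputed = raw + (raw / np.maximum(answered, 1)) * (n_items - answered)

    out = np.full(data.n, np.nan)
    complete = answered == n_items
    out[complete] = raw[complete]
    if allow_partial:
        partial = (~complete) & (answered >= min_answered)
        out[partial] = raw_imputed[partial]
    return 100.0 * (out - instrument.min_raw) / (instrument.max_raw - instrument.min_raw)
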
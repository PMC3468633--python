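"""Robust-design encounter histories: layout, validation, and the .inp dialect.

A robust-design study has widely spaced *primary* occasions (months; the
population is open between them) each containing tightly spaced *secondary*
occasions (days; the population is closed within them).  Every marked animal
carries one state-coded history with exactly one character per secondary
occasion:

    ``0`` not captured, ``F`` female, ``N`` non-caring male, ``C`` caring male.

Sexes never mix within a history, and within one primary occasion a male's
state cannot change (closure).  Encounter files follow a minimal MARK-style
dialect: optional ``/*`` comment lines, then one record per line,
``<codes> <frequency>;``.  Transect positions live in a sidecar CSV keyed by
``(individual_id, secondary_index)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
import yaml

FEMALE_CODES = frozenset("F")
MALE_CODES = frozenset("NC")
STATE_CODES = frozenset("FNC")
VALID_CODES = STATE_CODES | {"0"}

#: Months of the wet-warm season (October through March).
WET_WARM_MONTHS = frozenset({10, 11, 12, 1, 2, 3})


class FormatError(ValueError):
    """Malformed encounter file (wrong line length, bad frequency, ...)."""


class ValidationError(ValueError):
    """A history violates a structural invariant."""


class ClosureViolationError(ValidationError):
    """State change inside a closed secondary session."""


def season_from_month(label: str) -> str:
    """Season flag for a ``YYYY-MM`` month label.

    Returns ``"wet-warm"`` for October-March and ``"dry-cold"`` for
    April-September.
    """
    try:
        month = int(str(label).split("-")[1])
    except (IndexError, ValueError) as exc:
        raise ValueError(f"month label {label!r} is not of the form YYYY-MM") from exc
    if not 1 <= month <= 12:
        raise ValueError(f"month label {label!r} has month outside 1-12")
    return "wet-warm" if month in WET_WARM_MONTHS else "dry-cold"


@dataclass(frozen=True)
class RobustDesignLayout:
    """Primary/secondary occasion structure plus per-primary covariates.

    Parameters
    ----------
    month_labels
        Ordered ``YYYY-MM`` labels, one per primary occasion.
    secondaries
        Number of secondary occasions (sampling days) in each primary.
    occasion_temperature, occasion_rainfall
        Mean temperature (deg C) and rainfall (mm) over the sampling days of
        each primary; used as covariates for detection probability.
    interval_temperature, interval_rainfall
        Means over the days *between* consecutive primaries (length
        ``n_primary - 1``); used as covariates for survival and transition.
    """

    month_labels: tuple[str, ...]
    secondaries: tuple[int, ...]
    occasion_temperature: tuple[float, ...]
    occasion_rainfall: tuple[float, ...]
    interval_temperature: tuple[float, ...]
    interval_rainfall: tuple[float, ...]

    def __post_init__(self) -> None:
        n = len(self.month_labels)
        if n < 2:
            raise ValidationError("a robust design needs at least 2 primary occasions")
        if len(self.secondaries) != n:
            raise ValidationError("secondaries must have one entry per primary")
        if any(k < 1 for k in self.secondaries):
            raise ValidationError("every primary needs at least one secondary occasion")
        for name in ("occasion_temperature", "occasion_rainfall"):
            if len(getattr(self, name)) != n:
                raise ValidationError(f"{name} must have length n_primary")
        for name in ("interval_temperature", "interval_rainfall"):
            if len(getattr(self, name)) != n - 1:
                raise ValidationError(f"{name} must have length n_primary - 1")
        for label in self.month_labels:
            season_from_month(label)  # validates the label format

    @property
    def n_primary(self) -> int:
        return len(self.month_labels)

    @property
    def n_secondary(self) -> int:
        return int(sum(self.secondaries))

    @property
    def season(self) -> tuple[str, ...]:
        """Per-primary season flag, a pure function of the month label."""
        return tuple(season_from_month(m) for m in self.month_labels)

    @property
    def interval_season(self) -> tuple[str, ...]:
        """Season of each between-primary interval (taken from its start month)."""
        return tuple(season_from_month(m) for m in self.month_labels[:-1])

    def primary_slices(self) -> list[slice]:
        """Slice of the flat secondary-code string covered by each primary."""
        out, start = [], 0
        for k in self.secondaries:
            out.append(slice(start, start + k))
            start += k
        return out


@dataclass
class EncounterHistory:
    """One marked individual's state-coded record over all secondary occasions.

    ``positions`` maps secondary index -> transect position in metres (0-200)
    and may only be populated at captured occasions.
    """

    individual_id: str
    codes: tuple[str, ...]
    frequency: int = 1
    positions: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.codes = tuple(self.codes)
        bad = set(self.codes) - VALID_CODES
        if bad:
            raise ValidationError(
                f"history {self.individual_id}: illegal code(s) {sorted(bad)}"
            )
        observed = {c for c in self.codes if c != "0"}
        if not observed:
            raise ValidationError(
                f"history {self.individual_id}: no captures (histories are "
                "conditioned on first capture)"
            )
        if observed & FEMALE_CODES and observed & MALE_CODES:
            raise ValidationError(
                f"history {self.individual_id}: female and male codes mixed"
            )
        if self.frequency < 1:
            raise ValidationError(
                f"history {self.individual_id}: frequency must be positive"
            )
        for j in self.positions:
            if not 0 <= j < len(self.codes) or self.codes[j] == "0":
                raise ValidationError(
                    f"history {self.individual_id}: position at secondary {j} "
                    "does not align with a capture"
                )

    @property
    def group(self) -> str:
        """``"female"`` or ``"male"``, inferred from the code alphabet."""
        return "female" if set(self.codes) & FEMALE_CODES else "male"

    @property
    def code_string(self) -> str:
        return "".join(self.codes)


@dataclass(frozen=True)
class PrimarySummary:
    """Collapsed view of one primary occasion: state, detections, occasions."""

    observed_state: Optional[str]  # F | N | C | None
    captures: int
    k: int


def collapse_to_primary(
    history: EncounterHistory, layout: RobustDesignLayout
) -> list[PrimarySummary]:
    """Summarise a history per primary occasion, enforcing closure.

    Raises :class:`ClosureViolationError` if two different states appear
    within one closed session.
    """
    if len(history.codes) != layout.n_secondary:
        raise ValidationError(
            f"history {history.individual_id}: {len(history.codes)} codes for a "
            f"layout with {layout.n_secondary} secondary occasions"
        )
    out = []
    for t, sl in enumerate(layout.primary_slices()):
        chunk = [c for c in history.codes[sl] if c != "0"]
        states = set(chunk)
        if len(states) > 1:
            raise ClosureViolationError(
                f"history {history.individual_id}: states {sorted(states)} within "
                f"primary {t} (closed session)"
            )
        state = chunk[0] if chunk else None
        out.append(PrimarySummary(state, len(chunk), layout.secondaries[t]))
    return out


def _round_half_up(x: float, decimals: int = 1) -> float:
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def tabulate_parental_states(histories: Iterable[EncounterHistory]) -> pd.DataFrame:
    """Classify males as seen only non-caring, only caring, or in both states.

    Returns a DataFrame indexed by ``only_non_caring`` / ``only_caring`` /
    ``both`` with ``count`` and ``percent`` columns (percent rounded half-up
    to one decimal, weighting by history frequency).
    """
    counts = {"only_non_caring": 0, "only_caring": 0, "both": 0}
    for h in histories:
        if h.group != "male":
            continue
        states = {c for c in h.codes if c != "0"}
        if states == {"N"}:
            counts["only_non_caring"] += h.frequency
        elif states == {"C"}:
            counts["only_caring"] += h.frequency
        else:
            counts["both"] += h.frequency
    total = sum(counts.values())
    if total == 0:
        raise ValidationError("no male histories to tabulate")
    table = pd.DataFrame(
        {
            "count": pd.Series(counts),
            "percent": pd.Series(
                {k: _round_half_up(100.0 * v / total) for k, v in counts.items()}
            ),
        }
    )
    table.index.name = "state_usage"
    return table


# ---------------------------------------------------------------------------
# File I/O: the .inp dialect, the layout config, and the positions sidecar
# ---------------------------------------------------------------------------

def read_inp(path: str | Path, layout: RobustDesignLayout) -> list[EncounterHistory]:
    """Parse an encounter file against a layout.

    Each record is ``<codes> <frequency>;`` with codes over ``{0,F,N,C}`` of
    length ``layout.n_secondary``; the frequency column is optional and
    defaults to 1.  Lines starting with ``/*`` are comments.
    """
    path = Path(path)
    histories: list[EncounterHistory] = []
    n_codes = layout.n_secondary
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("/*"):
                continue
            record = line.rstrip(";").strip()
            parts = record.split()
            if len(parts) not in (1, 2):
                raise FormatError(f"{path.name}:{lineno}: expected '<codes> <freq>;'")
            codes = parts[0]
            if len(codes) != n_codes:
                raise FormatError(
                    f"{path.name}:{lineno}: history has {len(codes)} characters, "
                    f"layout requires {n_codes}"
                )
            if len(parts) == 2:
                try:
                    freq = int(parts[1])
                except ValueError as exc:
                    raise FormatError(
                        f"{path.name}:{lineno}: frequency {parts[1]!r} is not an integer"
                    ) from exc
            else:
                freq = 1
            try:
                h = EncounterHistory(
                    individual_id=f"h{len(histories) + 1}",
                    codes=tuple(codes),
                    frequency=freq,
                )
                collapse_to_primary(h, layout)  # closure check
            except ValidationError as exc:
                raise type(exc)(f"{path.name}:{lineno}: {exc}") from None
            histories.append(h)
    return histories


def write_inp(
    histories: Sequence[EncounterHistory],
    layout: RobustDesignLayout,
    path: str | Path,
) -> Path:
    """Write histories to the .inp dialect; inverse of :func:`read_inp`."""
    path = Path(path)
    lines = [f"/* {layout.n_primary} primary occasions, "
             f"{layout.n_secondary} secondary occasions */"]
    for h in histories:
        if len(h.codes) != layout.n_secondary:
            raise ValidationError(
                f"history {h.individual_id} does not match the layout"
            )
        lines.append(f"{h.code_string} {h.frequency};")
    path.write_text("\n".join(lines) + "\n")
    return path


def write_positions(histories: Sequence[EncounterHistory], path: str | Path) -> Path:
    """Write the transect-position sidecar CSV."""
    rows = [
        {"individual_id": h.individual_id, "secondary_index": j, "position_m": pos}
        for h in histories
        for j, pos in sorted(h.positions.items())
    ]
    frame = pd.DataFrame(rows, columns=["individual_id", "secondary_index", "position_m"])
    frame.to_csv(path, index=False)
    return Path(path)


def read_positions(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    expected = {"individual_id", "secondary_index", "position_m"}
    if not expected.issubset(frame.columns):
        raise FormatError(f"positions sidecar must have columns {sorted(expected)}")
    return frame


def write_layout(layout: RobustDesignLayout, path: str | Path) -> Path:
    """Serialise a layout to YAML (months with per-primary covariates, then
    per-interval covariates)."""
    doc = {
        "months": [
            {
                "label": layout.month_labels[t],
                "secondaries": int(layout.secondaries[t]),
                "temperature": float(layout.occasion_temperature[t]),
                "rainfall": float(layout.occasion_rainfall[t]),
            }
            for t in range(layout.n_primary)
        ],
        "intervals": [
            {
                "temperature": float(layout.interval_temperature[t]),
                "rainfall": float(layout.interval_rainfall[t]),
            }
            for t in range(layout.n_primary - 1)
        ],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))
    return Path(path)


def read_layout(path: str | Path) -> RobustDesignLayout:
    doc = yaml.safe_load(Path(path).read_text())
    months = doc["months"]
    intervals = doc.get("intervals")
    if intervals is None:
        # fall back to midpoints of adjacent occasion means
        intervals = [
            {
                "temperature": (months[t]["temperature"] + months[t + 1]["temperature"]) / 2,
                "rainfall": (months[t]["rainfall"] + months[t + 1]["rainfall"]) / 2,
            }
            for t in range(len(months) - 1)
        ]
    return RobustDesignLayout(
        month_labels=tuple(m["label"] for m in months),
        secondaries=tuple(int(m["secondaries"]) for m in months),
        occasion_temperature=tuple(float(m["temperature"]) for m in months),
        occasion_rainfall=tuple(float(m["rainfall"]) for m in months),
        interval_temperature=tuple(float(v["temperature"]) for v in intervals),
        interval_rainfall=tuple(float(v["rainfall"]) for v in intervals),
    )


def default_layout() -> RobustDesignLayout:
    """The one-year, 12-month / 46-day study layout.

    August through July, four sampling days per month except two
    heavy-rain months with three; occasion and interval covariates follow
    the site's seasonal climate (mean temperature 12-20 deg C, wet-warm
    season October-March with monthly rainfall several times the dry-cold
    season's).
    """
    labels = (
        "2003-08", "2003-09", "2003-10", "2003-11", "2003-12", "2004-01",
        "2004-02", "2004-03", "2004-04", "2004-05", "2004-06", "2004-07",
    )
    secondaries = (4, 4, 4, 3, 4, 4, 4, 4, 3, 4, 4, 4)
    temp = (14.0, 15.0, 16.5, 17.5, 19.0, 20.0, 19.5, 18.5, 17.0, 15.0, 13.0, 12.0)
    rain = (70.0, 90.0, 180.0, 220.0, 280.0, 320.0, 300.0, 240.0, 110.0, 80.0, 60.0, 55.0)
    i_temp = tuple((temp[t] + temp[t + 1]) / 2 for t in range(11))
    i_rain = tuple((rain[t] + rain[t + 1]) / 2 for t in range(11))
    return RobustDesignLayout(labels, secondaries, temp, rain, i_temp, i_rain)
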
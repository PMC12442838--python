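"""Long-format EMA tables and the preprocessing rules applied before model fitting.

One record is one person x occasion x item response: a 0-100 visual-analog
rating (or a 0/1 yes-no answer), a response time in seconds, the occasion's
activity checklist, and person-constant covariates.  Preprocessing:

* visual-analog ratings are dichotomized at the scale midpoint
  (0-49 -> 0, 50-100 -> 1);
* item responses with RTs longer than ``rt_cap`` seconds (default 30) are
  removed;
* occasions whose retained RTs show no variation (or with fewer than
  ``min_items`` retained items) are dropped, since the diffusion model
  requires RT variation within an occasion;
* the activity checklist is coded into momentary work and recovery flags;
* a traditional summary RT per occasion is the mean of the natural-log
  retained RTs.

All logarithms are natural logarithms.
"""
from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ACTIVITY_VOCABULARY",
    "RECOVERY_ACTIVITIES",
    "ItemSet",
    "EMARecord",
    "OccasionData",
    "SchemaError",
    "RowParseError",
    "read_long_table",
    "write_long_table",
    "dichotomize_rating",
    "apply_rt_filter",
    "assemble_occasions",
    "drop_invariant_rt_occasions",
    "code_activities",
    "mean_log_rt",
    "person_covariates",
    "preprocess",
    "occasions_to_frame",
]

ACTIVITY_VOCABULARY = frozenset(
    {
        "work",
        "chores",
        "leisure",
        "inactive",
        "interact with others",
        "eating",
        "drinking",
        "on the telephone",
        "other",
    }
)
RECOVERY_ACTIVITIES = frozenset(
    {"leisure", "inactive", "interact with others", "on the telephone"}
)

_COLUMNS = [
    "person_id",
    "occasion_id",
    "day",
    "item_id",
    "rating",
    "rt_seconds",
    "activities",
    "neuroticism",
    "depression",
]


class SchemaError(ValueError):
    """A mandatory column is missing or an item label is not declared."""


class RowParseError(ValueError):
    """A field failed to parse; carries the offending 1-based data row index."""

    def __init__(self, msg: str, row: int):
        super().__init__(msg)
        self.row = row


@dataclass(frozen=True)
class ItemSet:
    """A declared set of items sharing one response scale.

    scale: ``"vas"`` for 0-100 visual-analog ratings (dichotomized at the
    midpoint downstream) or ``"binary"`` for native 0/1 responses.
    """

    name: str
    items: tuple[str, ...]
    scale: str = "vas"

    def __post_init__(self):
        if self.scale not in ("vas", "binary"):
            raise ValueError(f"unknown scale {self.scale!r}")
        if len(self.items) != len(set(self.items)):
            raise ValueError("duplicate item ids in item set")


@dataclass(frozen=True)
class EMARecord:
    """One item response at one measurement occasion."""

    person_id: str
    occasion_id: int          # scheduled prompt index within person, 1-based
    day: int
    item_id: str
    rating: int               # 0..100 for vas items, 0/1 for binary items
    rt_seconds: float         # > 0
    activities: frozenset = field(default_factory=frozenset)
    neuroticism: float = float("nan")
    depression: float = float("nan")

    def __post_init__(self):
        if not self.rt_seconds > 0:
            raise ValueError(f"rt_seconds must be positive, got {self.rt_seconds}")


@dataclass
class OccasionData:
    """All retained item responses of one person-occasion, scoring-ready."""

    person_id: str
    occasion_id: int
    day: int
    binary_responses: dict
    rts: dict                 # item_id -> seconds; filtered items absent
    work: int = 0
    recovery: int = 0
    mean_log_rt: float = float("nan")


def dichotomize_rating(rating) -> int:
    """Midpoint split of the 0-100 scale: 0-49 -> 0, 50-100 -> 1."""
    r = float(rating)
    if not (0 <= r <= 100):
        raise ValueError(f"rating {rating!r} outside [0, 100]")
    return 0 if r <= 49 else 1


def code_activities(activities) -> tuple[int, int]:
    """Code the checklist into (work, recovery) flags.

    work = 1 iff "work" was checked; recovery = 1 iff any of leisure,
    inactive, interact with others, or on the telephone was checked.  The
    flags are independent: both may be 1.
    """
    labels = set(activities)
    unknown = labels - ACTIVITY_VOCABULARY
    if unknown:
        raise ValueError(f"unknown activity labels: {sorted(unknown)}")
    work = int("work" in labels)
    recovery = int(bool(labels & RECOVERY_ACTIVITIES))
    return work, recovery


def read_long_table(path, item_set: ItemSet) -> list[EMARecord]:
    """Read a long-format delimited table into records, preserving row order.

    The file must carry a header naming at least person_id, occasion_id,
    item_id, rating and rt_seconds; lines starting with ``#`` are ignored.
    """
    df = pd.read_csv(path, comment="#", dtype=str, keep_default_na=False)
    required = ["person_id", "occasion_id", "item_id", "rating", "rt_seconds"]
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"missing mandatory column {col!r}")
    known = set(item_set.items)
    records: list[EMARecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        d = row._asdict()
        item = d["item_id"]
        if item not in known:
            raise SchemaError(f"unknown item label {item!r} at row {i}")
        try:
            rt = float(d["rt_seconds"])
        except ValueError:
            raise RowParseError(
                f"non-numeric rt_seconds {d['rt_seconds']!r} at row {i}", row=i
            ) from None
        try:
            rating = int(float(d["rating"]))
            occ = int(float(d["occasion_id"]))
            day = int(float(d.get("day", 0) or 0))
        except ValueError as exc:
            raise RowParseError(f"{exc} at row {i}", row=i) from None
        acts = frozenset(
            a.strip() for a in d.get("activities", "").split(";") if a.strip()
        )
        records.append(
            EMARecord(
                person_id=d["person_id"],
                occasion_id=occ,
                day=day,
                item_id=item,
                rating=rating,
                rt_seconds=rt,
                activities=acts,
                neuroticism=float(d["neuroticism"]) if d.get("neuroticism") else float("nan"),
                depression=float(d["depression"]) if d.get("depression") else float("nan"),
            )
        )
    return records


def write_long_table(records, path, header_comment: str | None = None) -> None:
    """Write records as the long-format CSV that ``read_long_table`` accepts."""
    rows = [
        {
            "person_id": r.person_id,
            "occasion_id": r.occasion_id,
            "day": r.day,
            "item_id": r.item_id,
            "rating": r.rating,
            "rt_seconds": r.rt_seconds,
            "activities": ";".join(sorted(r.activities)),
            "neuroticism": r.neuroticism,
            "depression": r.depression,
        }
        for r in records
    ]
    df = pd.DataFrame(rows, columns=_COLUMNS)
    buf = io.StringIO()
    if header_comment:
        buf.write(f"# {header_comment}\n")
    df.to_csv(buf, index=False)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(buf.getvalue())


def apply_rt_filter(records, cap: float = 30.0):
    """Remove item responses with RTs strictly longer than ``cap`` seconds.

    Returns (retained records, number removed).  The boundary is read
    strictly: an RT equal to the cap is retained.
    """
    if not cap > 0:
        raise ValueError("cap must be positive")
    kept = [r for r in records if r.rt_seconds <= cap]
    return kept, len(records) - len(kept)


def mean_log_rt(occasion_or_rts) -> float:
    """Mean of the natural-log retained RTs of an occasion; NaN if none remain."""
    if isinstance(occasion_or_rts, OccasionData):
        rts = list(occasion_or_rts.rts.values())
    else:
        rts = list(occasion_or_rts)
    if not rts:
        return float("nan")
    return float(np.mean(np.log(rts)))


def assemble_occasions(records, item_set: ItemSet) -> list[OccasionData]:
    """Group RT-filtered records into person-occasions for the given item set.

    Dichotomizes vas ratings, codes activity flags, and computes the
    occasion's mean log RT.  Records for items outside the set are ignored.
    """
    groups: dict[tuple, OccasionData] = {}
    members = set(item_set.items)
    order: list[tuple] = []
    acts_by_key: dict[tuple, frozenset] = {}
    for r in records:
        if r.item_id not in members:
            continue
        key = (r.person_id, r.occasion_id)
        if key not in groups:
            groups[key] = OccasionData(
                person_id=r.person_id,
                occasion_id=r.occasion_id,
                day=r.day,
                binary_responses={},
                rts={},
            )
            order.append(key)
            acts_by_key[key] = r.activities
        occ = groups[key]
        if r.item_id in occ.binary_responses:
            raise ValueError(
                f"duplicate item {r.item_id!r} for person {r.person_id!r} "
                f"occasion {r.occasion_id}"
            )
        if item_set.scale == "vas":
            occ.binary_responses[r.item_id] = dichotomize_rating(r.rating)
        else:
            if r.rating not in (0, 1):
                raise ValueError(
                    f"binary item {r.item_id!r} has rating {r.rating!r}"
                )
            occ.binary_responses[r.item_id] = int(r.rating)
        occ.rts[r.item_id] = float(r.rt_seconds)
    out = []
    for key in order:
        occ = groups[key]
        occ.work, occ.recovery = code_activities(acts_by_key[key])
        occ.mean_log_rt = mean_log_rt(occ)
        out.append(occ)
    return out


def drop_invariant_rt_occasions(occasions, min_items: int = 2):
    """Drop occasions whose retained RTs show no variation.

    An occasion is removed iff fewer than ``min_items`` RTs remain or all
    remaining RTs are equal.  Returns (retained occasions, number removed).
    """
    kept = []
    for occ in occasions:
        vals = list(occ.rts.values())
        if len(vals) >= min_items and len(set(vals)) > 1:
            kept.append(occ)
    return kept, len(occasions) - len(kept)


def person_covariates(records) -> pd.DataFrame:
    """Person-level covariate table (neuroticism, depression) from records."""
    seen: dict[str, tuple] = {}
    for r in records:
        if r.person_id not in seen:
            seen[r.person_id] = (r.neuroticism, r.depression)
    return pd.DataFrame(
        [(p, n, d) for p, (n, d) in seen.items()],
        columns=["person_id", "neuroticism", "depression"],
    )


def preprocess(records, item_set: ItemSet, rt_cap: float = 30.0, min_items: int = 2):
    """Full preprocessing in the stated order: item-level RT cap first, then
    occasion assembly, then the no-variation occasion filter.

    Returns (occasions, accounting) where accounting records counts at every
    filter step.
    """
    in_set = [r for r in records if r.item_id in set(item_set.items)]
    filtered, n_rt_removed = apply_rt_filter(in_set, cap=rt_cap)
    occasions = assemble_occasions(filtered, item_set)
    n_assembled = len(occasions)
    occasions, n_occ_removed = drop_invariant_rt_occasions(occasions, min_items=min_items)
    accounting = {
        "item_set": item_set.name,
        "records_in_set": len(in_set),
        "records_removed_rt_cap": n_rt_removed,
        "occasions_assembled": n_assembled,
        "occasions_removed_invariant": n_occ_removed,
        "occasions_retained": len(occasions),
    }
    return occasions, accounting


def occasions_to_frame(occasions, item_set: ItemSet) -> pd.DataFrame:
    """Occasion-level table: binary responses, retained RTs, flags, mean log RT."""
    rows = []
    for occ in occasions:
        row = {
            "person_id": occ.person_id,
            "occasion_id": occ.occasion_id,
            "day": occ.day,
            "work": occ.work,
            "recovery": occ.recovery,
            "mean_log_rt": occ.mean_log_rt,
        }
        for item in item_set.items:
            row[f"x_{item}"] = occ.binary_responses.get(item, np.nan)
            row[f"rt_{item}"] = occ.rts.get(item, np.nan)
        rows.append(row)
    return pd.DataFrame(rows)
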
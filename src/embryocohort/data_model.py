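"""Domain types and CSV/JSON I/O for embryo-level IVF cycle data.

One *cohort* is the set of sibling embryos fertilized in a single IVF
treatment cycle.  Only one or two embryos per cycle are transferred to the
uterus and carry an implantation outcome; the cycle-level label is positive
iff every transferred embryo implanted (double transfers with discordant
outcomes are rejected as data errors).

Morphokinetic event times are stored in minutes from fertilization (t0 = 0).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional

import pandas as pd

__all__ = [
    "EVENTS",
    "CORE_EVENTS",
    "EXPANSION_LABELS",
    "ICM_TE_CATEGORIES",
    "GardnerScore",
    "EmbryoRecord",
    "Cohort",
    "SchemaError",
    "ValidationError",
    "derive_label",
    "read_dataset",
    "write_dataset",
    "cohorts_to_dataframe",
    "dataframe_to_cohorts",
    "cohorts_to_json",
]

#: All recognised morphokinetic events, in developmental order.
EVENTS = ("t0", "tPNf", "t2", "t3", "t4", "t7", "t8", "tM", "tSB")

#: The six events used for the kinetic feature vector (in developmental order).
CORE_EVENTS = ("t2", "t3", "t4", "t8", "tM", "tSB")

#: Blastocyst expansion grades 2-6 in the field's five-letter nomenclature
#: (early, full, expanded, hatching, hatched blastocyst); grade 1 is
#: pre-blastocyst and carries no letter label.
EXPANSION_LABELS = {2: "BT", 3: "BC", 4: "BE", 5: "BHi", 6: "BH"}

ICM_TE_CATEGORIES = ("A", "B", "C", "D")

CSV_COLUMNS = [
    "embryo_id", "cycle_id", "transferred", "implanted",
    "t0", "tPNf", "t2", "t3", "t4", "t7", "t8", "tM", "tSB",
    "exp", "icm", "te", "oocyte_age", "dl_confidence", "donor_cycle",
]


class SchemaError(ValueError):
    """A dataset file does not conform to the expected column schema."""


class ValidationError(ValueError):
    """A record or cohort violates a domain invariant."""


@dataclass(frozen=True)
class GardnerScore:
    """Three-part blastocyst quality score: expansion 1-6, ICM A-D, TE A-D.

    All three parts are mandatory; a partially annotated score is treated as
    absent upstream.
    """

    expansion: int
    icm: str
    te: str

    def __post_init__(self) -> None:
        if self.expansion not in range(1, 7):
            raise ValidationError(f"expansion grade must be 1-6, got {self.expansion!r}")
        for part, name in ((self.icm, "icm"), (self.te, "te")):
            if part not in ICM_TE_CATEGORIES:
                raise ValidationError(f"{name} must be one of A-D, got {part!r}")

    def as_tuple(self) -> tuple[int, str, str]:
        return (self.expansion, self.icm, self.te)

    @property
    def quality_rank(self) -> tuple[int, int, int]:
        """Orderable quality key: larger = better (A outranks D)."""
        return (
            self.expansion,
            3 - ICM_TE_CATEGORIES.index(self.icm),
            3 - ICM_TE_CATEGORIES.index(self.te),
        )


@dataclass
class EmbryoRecord:
    """One embryo of one IVF cycle.

    ``implanted`` is present exactly when ``transferred`` is true: only
    transferred embryos have an observable implantation outcome.
    ``morphokinetics`` maps event name -> minutes from fertilization; absent
    keys are missing annotations.
    """

    embryo_id: str
    cycle_id: str
    transferred: bool
    implanted: Optional[bool]
    morphokinetics: dict[str, float] = field(default_factory=dict)
    gardner: Optional[GardnerScore] = None
    oocyte_age: float = 35.0
    dl_confidence: Optional[float] = None
    donor_cycle: bool = False

    def __post_init__(self) -> None:
        if self.transferred and self.implanted is None:
            raise ValidationError(
                f"embryo {self.embryo_id}: transferred embryo must have an implantation outcome"
            )
        if not self.transferred and self.implanted is not None:
            raise ValidationError(
                f"embryo {self.embryo_id}: non-transferred embryo cannot have an outcome"
            )
        for event, t in self.morphokinetics.items():
            if event not in EVENTS:
                raise ValidationError(f"embryo {self.embryo_id}: unknown event {event!r}")
            if not math.isfinite(t) or t < 0:
                raise ValidationError(
                    f"embryo {self.embryo_id}: event {event} time must be finite and >= 0"
                )
        if "t0" in self.morphokinetics and self.morphokinetics["t0"] != 0.0:
            raise ValidationError(f"embryo {self.embryo_id}: t0 is fertilization, must be 0")
        if not (18.0 <= self.oocyte_age <= 51.0):
            raise ValidationError(
                f"embryo {self.embryo_id}: oocyte_age {self.oocyte_age} outside 18-51"
            )
        if self.dl_confidence is not None and not (0.0 <= self.dl_confidence <= 1.0):
            raise ValidationError(
                f"embryo {self.embryo_id}: dl_confidence must be in [0, 1]"
            )

    @property
    def blastulated(self) -> bool:
        """Whether this embryo reached the blastocyst stage.

        Determined from time-lapse (an annotated start-of-blastulation time)
        or from the presence of a Gardner score, which is only assigned at
        the blastocyst stage.
        """
        return "tSB" in self.morphokinetics or self.gardner is not None

    def copy(self) -> "EmbryoRecord":
        return replace(self, morphokinetics=dict(self.morphokinetics))


@dataclass
class Cohort:
    """All embryos of one IVF cycle plus the derived cycle-level label."""

    cycle_id: str
    embryos: list[EmbryoRecord]

    def __post_init__(self) -> None:
        if not self.embryos:
            raise ValidationError(f"cohort {self.cycle_id}: no embryos")
        for e in self.embryos:
            if e.cycle_id != self.cycle_id:
                raise ValidationError(
                    f"cohort {self.cycle_id}: embryo {e.embryo_id} belongs to {e.cycle_id}"
                )
        transferred = self.transferred_embryos
        if not 1 <= len(transferred) <= 2:
            raise ValidationError(
                f"cohort {self.cycle_id}: expected 1-2 transferred embryos, "
                f"found {len(transferred)}"
            )
        outcomes = {e.implanted for e in transferred}
        if len(outcomes) > 1:
            raise ValidationError(
                f"cohort {self.cycle_id}: discordant outcomes for double transfer"
            )
        ages = {e.oocyte_age for e in self.embryos}
        if len(ages) > 1:
            raise ValidationError(f"cohort {self.cycle_id}: oocyte_age differs across embryos")

    @property
    def transferred_embryos(self) -> list[EmbryoRecord]:
        return [e for e in self.embryos if e.transferred]

    @property
    def label(self) -> str:
        return derive_label(self)

    @property
    def size(self) -> int:
        return len(self.embryos)

    @property
    def oocyte_age(self) -> float:
        return self.embryos[0].oocyte_age

    @property
    def donor_cycle(self) -> bool:
        return self.embryos[0].donor_cycle

    def siblings_of(self, embryo_id: str) -> list[EmbryoRecord]:
        """All cohort embryos except the named one (order preserved)."""
        if embryo_id not in {e.embryo_id for e in self.embryos}:
            raise KeyError(f"embryo {embryo_id} not in cohort {self.cycle_id}")
        return [e for e in self.embryos if e.embryo_id != embryo_id]

    def copy(self) -> "Cohort":
        return Cohort(self.cycle_id, [e.copy() for e in self.embryos])


def derive_label(cohort: Cohort) -> str:
    """Cycle label: ``"positive"`` iff every transferred embryo implanted."""
    transferred = cohort.transferred_embryos
    if not transferred:
        raise ValidationError(f"cohort {cohort.cycle_id}: no transferred embryo")
    return "positive" if all(e.implanted for e in transferred) else "negative"


# ---------------------------------------------------------------------------
# CSV / JSON I/O
# ---------------------------------------------------------------------------

_EVENT_COLUMNS = ["t0", "tPNf", "t2", "t3", "t4", "t7", "t8", "tM", "tSB"]


def _bool_to_cell(v: Optional[bool]) -> str:
    return "" if v is None else ("true" if v else "false")


def _cell_to_bool(v: object, column: str) -> Optional[bool]:
    if v is None or (isinstance(v, float) and math.isnan(v)) or v == "":
        return None
    s = str(v).strip().lower()
    if s in ("true", "1", "1.0"):
        return True
    if s in ("false", "0", "0.0"):
        return False
    raise SchemaError(f"column {column}: cannot parse boolean from {v!r}")


def cohorts_to_dataframe(cohorts: Iterable[Cohort]) -> pd.DataFrame:
    """Flatten cohorts to the canonical one-row-per-embryo table."""
    rows = []
    for cohort in cohorts:
        for e in cohort.embryos:
            row: dict[str, object] = {
                "embryo_id": e.embryo_id,
                "cycle_id": e.cycle_id,
                "transferred": _bool_to_cell(e.transferred),
                "implanted": _bool_to_cell(e.implanted),
                "oocyte_age": e.oocyte_age,
                "dl_confidence": "" if e.dl_confidence is None else e.dl_confidence,
                "donor_cycle": _bool_to_cell(e.donor_cycle),
                "exp": "" if e.gardner is None else e.gardner.expansion,
                "icm": "" if e.gardner is None else e.gardner.icm,
                "te": "" if e.gardner is None else e.gardner.te,
            }
            for ev in _EVENT_COLUMNS:
                row[ev] = e.morphokinetics.get(ev, "")
            rows.append(row)
    return pd.DataFrame(rows, columns=CSV_COLUMNS)


def dataframe_to_cohorts(df: pd.DataFrame) -> list[Cohort]:
    """Group a one-row-per-embryo table into validated cohorts."""
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory columns: {missing}")

    cohorts: dict[str, list[EmbryoRecord]] = {}
    for _, row in df.iterrows():
        morphokinetics = {}
        for ev in _EVENT_COLUMNS:
            v = row[ev]
            if v is None or v == "" or (isinstance(v, float) and math.isnan(v)):
                continue
            morphokinetics[ev] = float(v)
        exp, icm, te = row["exp"], row["icm"], row["te"]
        has_gardner = not (
            exp is None or exp == "" or (isinstance(exp, float) and math.isnan(exp))
        )
        gardner = None
        if has_gardner:
            gardner = GardnerScore(int(float(exp)), str(icm).strip(), str(te).strip())
        dl = row["dl_confidence"]
        dl_missing = dl is None or dl == "" or (isinstance(dl, float) and math.isnan(dl))
        record = EmbryoRecord(
            embryo_id=str(row["embryo_id"]),
            cycle_id=str(row["cycle_id"]),
            transferred=bool(_cell_to_bool(row["transferred"], "transferred")),
            implanted=_cell_to_bool(row["implanted"], "implanted"),
            morphokinetics=morphokinetics,
            gardner=gardner,
            oocyte_age=float(row["oocyte_age"]),
            dl_confidence=None if dl_missing else float(dl),
            donor_cycle=bool(_cell_to_bool(row["donor_cycle"], "donor_cycle")),
        )
        cohorts.setdefault(record.cycle_id, []).append(record)
    return [Cohort(cid, embryos) for cid, embryos in cohorts.items()]


def read_dataset(path: str, format: str = "csv") -> list[Cohort]:
    """Read a one-row-per-embryo CSV file into validated cohorts.

    Missing values are empty cells; event times are minutes from
    fertilization.  A double transfer with discordant outcomes raises
    :class:`ValidationError` naming the cycle.
    """
    if format != "csv":
        raise ValueError(f"unsupported format: {format!r}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    return dataframe_to_cohorts(df)


def write_dataset(cohorts: Iterable[Cohort], path: str) -> None:
    """Write cohorts to CSV; ``read_dataset`` round-trips field-for-field."""
    cohorts_to_dataframe(cohorts).to_csv(path, index=False)


def cohorts_to_json(cohorts: Iterable[Cohort], path: Optional[str] = None) -> str:
    """Serialise cohorts to a JSON document (report artifact export)."""
    payload = []
    for c in cohorts:
        payload.append(
            {
                "cycle_id": c.cycle_id,
                "label": c.label,
                "embryos": [
                    {
                        "embryo_id": e.embryo_id,
                        "transferred": e.transferred,
                        "implanted": e.implanted,
                        "morphokinetics": e.morphokinetics,
                        "gardner": None if e.gardner is None else list(e.gardner.as_tuple()),
                        "oocyte_age": e.oocyte_age,
                        "dl_confidence": e.dl_confidence,
                        "donor_cycle": e.donor_cycle,
                    }
                    for e in c.embryos
                ],
            }
        )
    text = json.dumps(payload, indent=2, sort_keys=True)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text
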
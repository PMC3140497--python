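"""Data model, tabular I/O, and filtering/aggregation rules for prey surveys.

The raw unit of data is a single prey encounter made by a diver on either a
belt transect or an unmeasured verification dive, under one of two sampling
modes: ``sponging`` (probing the substrate with a sponge, emulating the
dolphin foraging tactic) or ``non_sponging`` (filming the undisturbed
substrate).  This module turns a flat file of such encounters into
analysis-ready family-by-mode abundance tables:

* parse and validate observation and family-annotation files,
* drop small prey (below a length threshold) and unidentifiable prey,
* roll species-level encounters up to the family level,
* average transect replicates into a single per-transect value, and
* pool counts for descriptive (all dives) or inferential (transects only)
  use.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Mapping, Optional, Sequence

import pandas as pd

__all__ = [
    "UNKNOWN_FAMILY",
    "Mode",
    "SiteKind",
    "Scope",
    "SchemaError",
    "DataConflictError",
    "ContractViolation",
    "PreyObservation",
    "FamilyAnnotation",
    "FamilyUniverse",
    "FilterConfig",
    "AbundanceTable",
    "canonical_family",
    "read_observations",
    "write_observations",
    "read_family_annotations",
    "write_family_annotations",
    "apply_filters",
    "rollup_to_family",
    "average_replicates",
    "pool_counts",
]

UNKNOWN_FAMILY = "UNKNOWN"

Mode = Literal["sponging", "non_sponging"]
SiteKind = Literal["transect", "verification"]
Scope = Literal["transects_only", "all_dives"]

MODES: tuple[str, ...] = ("sponging", "non_sponging")
SITE_KINDS: tuple[str, ...] = ("transect", "verification")

OBSERVATION_COLUMNS = (
    "dive_id",
    "site_kind",
    "transect_id",
    "replicate",
    "mode",
    "family",
    "species",
    "length_cm",
    "identified",
)

ANNOTATION_COLUMNS = ("family", "has_swimbladder", "evidence")

_TRUE_TOKENS = {"y", "yes", "true", "1", "t"}
_FALSE_TOKENS = {"n", "no", "false", "0", "f"}


class SchemaError(ValueError):
    """A file or record does not match the documented schema."""


class DataConflictError(ValueError):
    """Two records assert contradictory facts (e.g. swimbladder status)."""


class ContractViolation(ValueError):
    """An operation was called on data that violates its precondition."""


def canonical_family(name: str) -> str:
    """Normalize a family name: collapse whitespace, capitalize.

    Matching is by exact name after this normalization, so ``" dasyatidae "``
    and ``"Dasyatidae"`` refer to the same family.  The sentinel
    ``UNKNOWN`` (any case) is preserved verbatim.
    """
    s = " ".join(name.split())
    if not s:
        return s
    if s.casefold() == UNKNOWN_FAMILY.casefold():
        return UNKNOWN_FAMILY
    return s[:1].upper() + s[1:].lower()


@dataclass(frozen=True)
class PreyObservation:
    """One prey encounter with its sampling context.

    Attributes
    ----------
    dive_id
        Opaque identifier of the dive the encounter belongs to.
    site_kind
        ``"transect"`` (systematic belt transect) or ``"verification"``
        (unmeasured dive confirming the transect prey list).
    transect_id
        Transect identifier; required when ``site_kind == "transect"``.
    replicate
        Positive pass number (transects were swum twice for repeatability).
    mode
        ``"sponging"`` or ``"non_sponging"``.
    family
        Taxonomic family, or ``UNKNOWN`` for unidentifiable prey.
    species
        Optional binomial name, when identified below family.
    length_cm
        Estimated total length in cm, if one was made.
    identified
        Whether the prey could be identified at least to family.
    """

    dive_id: str
    site_kind: str
    transect_id: Optional[str]
    replicate: int
    mode: str
    family: str
    species: Optional[str] = None
    length_cm: Optional[float] = None
    identified: bool = True

    def __post_init__(self) -> None:
        if self.site_kind not in SITE_KINDS:
            raise SchemaError(
                f"site_kind must be one of {SITE_KINDS}, got {self.site_kind!r}"
            )
        if self.mode not in MODES:
            raise SchemaError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.site_kind == "transect" and not self.transect_id:
            raise SchemaError("transect observations require a transect_id")
        if self.replicate < 1:
            raise SchemaError(f"replicate must be >= 1, got {self.replicate}")
        if not self.identified and self.family != UNKNOWN_FAMILY:
            raise SchemaError(
                "unidentified prey must carry family=UNKNOWN, got "
                f"family={self.family!r}"
            )
        if self.length_cm is not None and not self.length_cm > 0:
            raise SchemaError(f"length_cm must be > 0, got {self.length_cm}")
        object.__setattr__(self, "family", canonical_family(self.family))


@dataclass(frozen=True)
class FamilyAnnotation:
    """Swimbladder status of one prey family, with its evidence tag."""

    family: str
    has_swimbladder: bool
    evidence: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "family", canonical_family(self.family))


class FamilyUniverse:
    """Catalog of prey families with definite swimbladder status.

    Serves both as the annotation lookup for the ratio statistic and as the
    null universe for the family-resampling test (the study's universe has
    29 families).  Duplicate annotations with identical status merge;
    conflicting status raises :class:`DataConflictError`.
    """

    def __init__(self, annotations: Iterable[FamilyAnnotation] = ()) -> None:
        self._by_family: dict[str, FamilyAnnotation] = {}
        for ann in annotations:
            self.add(ann)

    def add(self, ann: FamilyAnnotation) -> None:
        existing = self._by_family.get(ann.family)
        if existing is not None:
            if existing.has_swimbladder != ann.has_swimbladder:
                raise DataConflictError(
                    f"conflicting swimbladder status for family {ann.family!r}"
                )
            return
        self._by_family[ann.family] = ann

    @property
    def families(self) -> list[str]:
        """Family names in sorted order (the deterministic iteration order)."""
        return sorted(self._by_family)

    @property
    def size(self) -> int:
        return len(self._by_family)

    @property
    def n_no_swimbladder(self) -> int:
        return sum(1 for a in self._by_family.values() if not a.has_swimbladder)

    def __len__(self) -> int:
        return len(self._by_family)

    def __contains__(self, family: str) -> bool:
        return canonical_family(family) in self._by_family

    def __iter__(self):
        return iter(self.families)

    def has_swimbladder(self, family: str) -> bool:
        key = canonical_family(family)
        try:
            return self._by_family[key].has_swimbladder
        except KeyError:
            raise KeyError(f"family {family!r} is not annotated") from None

    def annotation(self, family: str) -> FamilyAnnotation:
        return self._by_family[canonical_family(family)]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FamilyUniverse):
            return NotImplemented
        return self._by_family == other._by_family


@dataclass(frozen=True)
class FilterConfig:
    """Exclusion rules applied to raw observations.

    ``min_length_cm`` removes prey strictly shorter than the threshold
    (default 7 cm: prey this small are obtainable at the surface in all
    habitats and are not plausible sponge-foraging targets).
    ``drop_unidentified`` removes prey that could not be identified to
    family.  Observations with no length estimate are retained.
    """

    min_length_cm: float = 7.0
    drop_unidentified: bool = True

    def __post_init__(self) -> None:
        if self.min_length_cm < 0:
            raise SchemaError("min_length_cm must be >= 0")


# AbundanceTable cells live in a DataFrame with one row per occupied cell.
CELL_INDEX = ["family", "mode", "site_kind", "transect_id", "replicate"]


@dataclass
class AbundanceTable:
    """Counts per (family, mode, site_kind, transect, replicate) cell.

    Counts are non-negative integers before replicate averaging and
    non-negative rationals after.  ``provenance`` records the filters and
    transforms that produced the table.
    """

    cells: pd.DataFrame
    provenance: str = ""

    def __post_init__(self) -> None:
        missing = [c for c in CELL_INDEX + ["count"] if c not in self.cells.columns]
        if missing:
            raise SchemaError(f"abundance table missing columns: {missing}")
        if (self.cells["count"] < 0).any():
            raise SchemaError("abundance counts must be non-negative")

    @property
    def total(self) -> float:
        return float(self.cells["count"].sum())

    def restrict(self, site_kind: str) -> "AbundanceTable":
        sub = self.cells[self.cells["site_kind"] == site_kind].reset_index(drop=True)
        return AbundanceTable(sub, provenance=f"{self.provenance}; restrict={site_kind}")

    def transect_ids(self) -> list[str]:
        ids = self.cells.loc[self.cells["site_kind"] == "transect", "transect_id"]
        return sorted(ids.dropna().unique())


def _parse_bool(token: str, *, context: str) -> bool:
    t = token.strip().casefold()
    if t in _TRUE_TOKENS:
        return True
    if t in _FALSE_TOKENS:
        return False
    raise SchemaError(f"{context}: cannot parse boolean from {token!r}")


def _opt(value) -> Optional[str]:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    s = str(value).strip()
    return s or None


def read_observations(path: str | Path, *, delimiter: str = ",") -> list[PreyObservation]:
    """Read an observation file into a list of :class:`PreyObservation`.

    The file is delimited text with header
    ``dive_id,site_kind,transect_id,replicate,mode,family,species,length_cm,identified``;
    empty strings mark missing optional fields.  Row order is preserved.
    Malformed rows are reported together with their 1-based line numbers.
    """
    path = Path(path)
    frame = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    missing = [c for c in OBSERVATION_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")

    observations: list[PreyObservation] = []
    errors: list[str] = []
    for i, row in enumerate(frame.itertuples(index=False)):
        line_no = i + 2  # header is line 1
        try:
            length_raw = _opt(getattr(row, "length_cm"))
            if length_raw is not None:
                try:
                    length = float(length_raw)
                except ValueError:
                    raise SchemaError(f"non-numeric length_cm {length_raw!r}")
            else:
                length = None
            obs = PreyObservation(
                dive_id=str(getattr(row, "dive_id")).strip(),
                site_kind=str(getattr(row, "site_kind")).strip(),
                transect_id=_opt(getattr(row, "transect_id")),
                replicate=int(str(getattr(row, "replicate")).strip()),
                mode=str(getattr(row, "mode")).strip(),
                family=str(getattr(row, "family")).strip() or UNKNOWN_FAMILY,
                species=_opt(getattr(row, "species")),
                length_cm=length,
                identified=_parse_bool(
                    str(getattr(row, "identified")), context="identified"
                ),
            )
        except (SchemaError, ValueError) as exc:
            errors.append(f"line {line_no}: {exc}")
            continue
        observations.append(obs)
    if errors:
        raise SchemaError(f"{path}: {len(errors)} malformed row(s): " + "; ".join(errors))
    return observations


def write_observations(obs: Sequence[PreyObservation], path: str | Path) -> Path:
    """Write observations in the format read by :func:`read_observations`."""
    path = Path(path)
    rows = [
        {
            "dive_id": o.dive_id,
            "site_kind": o.site_kind,
            "transect_id": o.transect_id or "",
            "replicate": o.replicate,
            "mode": o.mode,
            "family": o.family,
            "species": o.species or "",
            "length_cm": "" if o.length_cm is None else repr(float(o.length_cm)),
            "identified": str(o.identified).lower(),
        }
        for o in obs
    ]
    frame = pd.DataFrame(rows, columns=list(OBSERVATION_COLUMNS))
    frame.to_csv(path, index=False)
    return path


def read_family_annotations(path: str | Path, *, delimiter: str = ",") -> FamilyUniverse:
    """Read a family-annotation file into a :class:`FamilyUniverse`.

    Expects header ``family,has_swimbladder,evidence`` with
    ``has_swimbladder`` in {Y, N, true, false, 1, 0}.  Duplicate rows for a
    family (e.g. two congeners listed separately) merge when their status
    agrees and raise :class:`DataConflictError` when it does not.
    """
    path = Path(path)
    frame = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    missing = [c for c in ("family", "has_swimbladder") if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")
    universe = FamilyUniverse()
    for i, row in enumerate(frame.itertuples(index=False)):
        family = str(getattr(row, "family")).strip()
        if not family:
            raise SchemaError(f"{path}: line {i + 2}: empty family name")
        status = _parse_bool(
            str(getattr(row, "has_swimbladder")), context=f"{path}: line {i + 2}"
        )
        evidence = str(getattr(row, "evidence", "")).strip()
        universe.add(FamilyAnnotation(family, status, evidence))
    return universe


def write_family_annotations(universe: FamilyUniverse, path: str | Path) -> Path:
    """Write a universe in the format read by :func:`read_family_annotations`."""
    path = Path(path)
    rows = [
        {
            "family": f,
            "has_swimbladder": "Y" if universe.annotation(f).has_swimbladder else "N",
            "evidence": universe.annotation(f).evidence,
        }
        for f in universe.families
    ]
    frame = pd.DataFrame(rows, columns=list(ANNOTATION_COLUMNS))
    frame.to_csv(path, index=False)
    return path


def apply_filters(
    obs: Sequence[PreyObservation], cfg: FilterConfig = FilterConfig()
) -> list[PreyObservation]:
    """Apply the exclusion rules; idempotent, never adds rows.

    Removes observations strictly shorter than ``min_length_cm`` and, when
    ``drop_unidentified``, observations not identified to family.  Prey with
    no length estimate are retained (only prey known or estimated to be
    small were excluded from the study data).
    """

    def keep(o: PreyObservation) -> bool:
        if cfg.drop_unidentified and not o.identified:
            return False
        if o.length_cm is not None and o.length_cm < cfg.min_length_cm:
            return False
        return True

    return [o for o in obs if keep(o)]


def rollup_to_family(obs: Sequence[PreyObservation]) -> AbundanceTable:
    """Count observations per (family, mode, site_kind, transect, replicate).

    All analyses operate at the family level; every observation must already
    be identified to family (run :func:`apply_filters` first).
    """
    unknown = sum(1 for o in obs if o.family == UNKNOWN_FAMILY)
    if unknown:
        raise ContractViolation(
            f"{unknown} observation(s) have family=UNKNOWN; apply filters before rollup"
        )
    counter: Counter[tuple] = Counter(
        (o.family, o.mode, o.site_kind, o.transect_id, o.replicate) for o in obs
    )
    rows = [
        dict(zip(CELL_INDEX, key), count=count)
        for key, count in sorted(counter.items(), key=lambda kv: tuple(map(str, kv[0])))
    ]
    frame = pd.DataFrame(rows, columns=CELL_INDEX + ["count"])
    return AbundanceTable(frame, provenance="rollup_to_family")


def average_replicates(
    table: AbundanceTable, *, n_replicates: Optional[int] = None
) -> AbundanceTable:
    """Average replicate passes into a single value per transect cell.

    The table must contain only transect cells.  A family absent from one
    replicate contributes zero to that replicate, so with 2 replicates a
    family seen 4 times in one pass and never in the other averages to 2.
    The replicate index collapses to the single pseudo-replicate 1.

    ``n_replicates`` overrides the divisor; by default it is the number of
    distinct replicate ids present anywhere in the table (every transect and
    mode were sampled on each occasion).
    """
    if (table.cells["site_kind"] != "transect").any():
        raise ContractViolation("average_replicates requires a transects-only table")
    cells = table.cells
    if cells.empty:
        return AbundanceTable(cells.copy(), provenance=f"{table.provenance}; averaged")
    if n_replicates is None:
        n_replicates = int(cells["replicate"].nunique())
    grouped = (
        cells.groupby(["family", "mode", "transect_id"], as_index=False)["count"]
        .sum()
        .assign(count=lambda d: d["count"] / n_replicates)
    )
    grouped["site_kind"] = "transect"
    grouped["replicate"] = 1
    frame = grouped[CELL_INDEX + ["count"]].sort_values(CELL_INDEX).reset_index(drop=True)
    return AbundanceTable(
        frame, provenance=f"{table.provenance}; averaged over {n_replicates} replicates"
    )


def pool_counts(
    table: AbundanceTable, scope: Scope = "all_dives"
) -> dict[tuple[str, str], float]:
    """Sum cells over the selected scope into a (family, mode) -> count map.

    ``all_dives`` pools transects and verification dives (descriptive view;
    use raw, un-averaged integer counts); ``transects_only`` pools the
    systematic transect data (inferential view).  Per-mode totals equal the
    number of retained observations in scope before averaging.
    """
    cells = table.cells
    if scope == "transects_only":
        cells = cells[cells["site_kind"] == "transect"]
    elif scope != "all_dives":
        raise ValueError(f"unknown scope {scope!r}")
    pooled = cells.groupby(["family", "mode"])["count"].sum()
    return {
        (family, mode): float(count) for (family, mode), count in pooled.items()
    }
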
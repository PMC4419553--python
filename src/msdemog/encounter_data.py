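"""Encounter-history data structures, readers/writers and validation.

The observation unit is the breeding season: a season labelled ``Y`` spans
November of calendar year ``Y`` to October of ``Y+1``, and the census point
is the start of the season, so chicks fledging in season ``Y`` are not
population members at census ``Y``.  Each banded individual carries one
observation code per season:

====  =========================================================
code  meaning
====  =========================================================
(empty)  not seen at the colony
PB    seen at the colony as a pre-breeder
BS    seen breeding, attempt succeeded (chick fledged)
BF    seen breeding, attempt failed
NB    seen at the colony as a non-breeding adult
DEAD  recovered dead
C     banded as a chick (only in the fledge season's column)
====  =========================================================
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "ObservationCode",
    "IndividualHistory",
    "StudyDataset",
    "ValidationError",
    "ParseError",
    "read_encounter_table",
    "write_encounter_table",
    "summarize_dataset",
]


class ParseError(ValueError):
    """Malformed encounter table (bad code, missing column...)."""


class ValidationError(ValueError):
    """Structurally parseable but semantically invalid dataset."""


class ObservationCode(Enum):
    NOT_SEEN = ""
    SEEN_PREBREEDER = "PB"
    SEEN_BREEDER_SUCCESS = "BS"
    SEEN_BREEDER_FAIL = "BF"
    SEEN_NONBREEDER = "NB"
    RECOVERED_DEAD = "DEAD"

    @classmethod
    def from_token(cls, token: str) -> "ObservationCode":
        token = token.strip().upper()
        try:
            return cls(token)
        except ValueError:
            raise ParseError(f"unknown observation code {token!r}") from None


#: codes that mean the bird was seen alive at the colony
LIVE_SEEN_CODES = frozenset(
    {
        ObservationCode.SEEN_PREBREEDER,
        ObservationCode.SEEN_BREEDER_SUCCESS,
        ObservationCode.SEEN_BREEDER_FAIL,
        ObservationCode.SEEN_NONBREEDER,
    }
)

#: valid states at first detection for birds that enter the study as adults
_ADULT_ENTRY = {
    ObservationCode.SEEN_PREBREEDER: "PB",
    ObservationCode.SEEN_BREEDER_SUCCESS: "BS",
    ObservationCode.SEEN_BREEDER_FAIL: "BF",
    ObservationCode.SEEN_NONBREEDER: "NB",
}

CHICK_ENTRY = "chick"


@dataclass
class IndividualHistory:
    """One bird: identity, entry information and per-season codes.

    ``fledge_season`` is ``None`` for unknown-age birds (immigrants or
    visitors); these are parsed and kept but flagged so analysis datasets
    can exclude them, mirroring standard practice when age structure is
    modelled.  ``observations`` holds the post-entry seasons only; the
    entry itself (banding as chick, or the first resighting for birds
    already alive when the study window opens) is recorded by
    ``entry_season``/``entry_state``.
    """

    band_id: str
    sex: str  # 'M', 'F' or 'U'
    fledge_season: int | None
    entry_season: int
    entry_state: str  # 'chick', 'PB', 'BS', 'BF' or 'NB'
    observations: dict[int, ObservationCode] = field(default_factory=dict)

    @property
    def known_age(self) -> bool:
        return self.fledge_season is not None

    def age_at(self, season: int) -> int:
        if self.fledge_season is None:
            raise ValidationError(f"{self.band_id}: age unknown")
        return season - self.fledge_season

    def validate(self) -> None:
        if self.sex not in ("M", "F", "U"):
            raise ValidationError(f"{self.band_id}: bad sex {self.sex!r}")
        if self.entry_state not in (CHICK_ENTRY, "PB", "BS", "BF", "NB"):
            raise ValidationError(
                f"{self.band_id}: bad entry state {self.entry_state!r}"
            )
        if self.entry_state == CHICK_ENTRY:
            if self.fledge_season is None:
                raise ValidationError(
                    f"{self.band_id}: chick entry requires a fledge season"
                )
            if self.entry_season != self.fledge_season:
                raise ValidationError(
                    f"{self.band_id}: chick entry season must equal fledge season"
                )
        if self.fledge_season is not None and self.entry_season < self.fledge_season:
            raise ValidationError(
                f"{self.band_id}: entry season precedes fledge season"
            )
        dead_seen = None
        for season in sorted(self.observations):
            code = self.observations[season]
            if season < self.entry_season or (
                self.entry_state == CHICK_ENTRY and season == self.entry_season
            ):
                raise ValidationError(
                    f"{self.band_id}: observation in season {season} precedes entry"
                )
            if dead_seen is not None:
                raise ValidationError(
                    f"{self.band_id}: code after RECOVERED_DEAD in season {season}"
                )
            if code is ObservationCode.RECOVERED_DEAD:
                dead_seen = season


@dataclass
class StudyDataset:
    """A collection of encounter histories over a contiguous season range."""

    individuals: list[IndividualHistory]
    seasons: list[int]

    def validate(self) -> None:
        if sorted(self.seasons) != list(
            range(min(self.seasons), max(self.seasons) + 1)
        ):
            raise ValidationError("seasons must be contiguous")
        seen_ids: set[str] = set()
        for ind in self.individuals:
            if ind.band_id in seen_ids:
                raise ValidationError(f"duplicate band_id {ind.band_id!r}")
            seen_ids.add(ind.band_id)
            ind.validate()
            for season in ind.observations:
                if season not in self.seasons:
                    raise ValidationError(
                        f"{ind.band_id}: season {season} outside study range"
                    )
            if ind.entry_season not in self.seasons:
                raise ValidationError(
                    f"{ind.band_id}: entry season {ind.entry_season} outside range"
                )

    def known_age(self) -> "StudyDataset":
        """Analysis subset: unknown-age birds excluded (flagged, not lost)."""
        return StudyDataset(
            individuals=[i for i in self.individuals if i.known_age],
            seasons=list(self.seasons),
        )

    @property
    def unknown_age_ids(self) -> list[str]:
        return [i.band_id for i in self.individuals if not i.known_age]

    def __len__(self) -> int:
        return len(self.individuals)


def _parse_wide(rows: list[list[str]], header: list[str]) -> StudyDataset:
    fixed = ["band_id", "sex", "fledge_season"]
    if [h.strip() for h in header[:3]] != fixed:
        raise ParseError(f"header must start with {fixed}, got {header[:3]}")
    try:
        seasons = [int(h) for h in header[3:]]
    except ValueError as exc:
        raise ParseError(f"season columns must be integer labels: {exc}") from None
    individuals = []
    for rownum, row in enumerate(rows, start=2):
        if not row or all(not c.strip() for c in row):
            continue
        if len(row) != len(header):
            raise ParseError(f"row {rownum}: expected {len(header)} fields")
        band_id, sex, fledge_tok = (c.strip() for c in row[:3])
        sex = sex.upper() or "U"
        fledge = None if fledge_tok.upper() in ("", "U") else int(fledge_tok)
        obs: dict[int, ObservationCode] = {}
        entry_season = None
        entry_state = None
        for season, cell in zip(seasons, row[3:]):
            token = cell.strip().upper()
            if not token:
                continue
            if token == "C":
                if fledge is not None and season != fledge:
                    raise ParseError(
                        f"row {rownum} ({band_id}): 'C' outside fledge season"
                    )
                fledge = season
                entry_season, entry_state = season, CHICK_ENTRY
                continue
            try:
                code = ObservationCode.from_token(token)
            except ParseError:
                raise ParseError(
                    f"row {rownum} ({band_id}), season {season}: "
                    f"unknown code {token!r}"
                ) from None
            obs[season] = code
        if entry_season is None:
            if not obs:
                raise ParseError(f"row {rownum} ({band_id}): no observations")
            first = min(obs)
            code = obs[first]
            if code not in _ADULT_ENTRY:
                raise ParseError(
                    f"row {rownum} ({band_id}): first code {code.value!r} "
                    "cannot start a history"
                )
            entry_season, entry_state = first, _ADULT_ENTRY[code]
        individuals.append(
            IndividualHistory(band_id, sex, fledge, entry_season, entry_state, obs)
        )
    if not individuals:
        return StudyDataset([], seasons)
    return StudyDataset(individuals, seasons)


def _parse_long(rows: list[list[str]], header: list[str]) -> StudyDataset:
    # dialect: one (band_id, sex, fledge_season, season, code) triple-ish row
    # per sighting; seasons range inferred from data
    need = ["band_id", "sex", "fledge_season", "season", "code"]
    if [h.strip() for h in header] != need:
        raise ParseError(f"long format header must be {need}")
    by_bird: dict[str, dict] = {}
    for rownum, row in enumerate(rows, start=2):
        if not row or all(not c.strip() for c in row):
            continue
        band_id, sex, fledge_tok, season_tok, code_tok = (c.strip() for c in row)
        rec = by_bird.setdefault(
            band_id,
            {
                "sex": sex.upper() or "U",
                "fledge": None
                if fledge_tok.upper() in ("", "U")
                else int(fledge_tok),
                "cells": [],
            },
        )
        rec["cells"].append((int(season_tok), code_tok, rownum))
    seasons_seen: set[int] = set()
    wide_rows = []
    for band_id, rec in by_bird.items():
        for season, _, _ in rec["cells"]:
            seasons_seen.add(season)
    if not seasons_seen:
        raise ParseError("long table has no data rows")
    seasons = list(range(min(seasons_seen), max(seasons_seen) + 1))
    for band_id, rec in by_bird.items():
        cells = {s: tok for s, tok, _ in rec["cells"]}
        fl = rec["fledge"]
        row = [band_id, rec["sex"], "" if fl is None else str(fl)]
        row += [cells.get(s, "") for s in seasons]
        wide_rows.append(row)
    header = ["band_id", "sex", "fledge_season"] + [str(s) for s in seasons]
    return _parse_wide(wide_rows, header)


def read_encounter_table(
    path, *, delimiter: str | None = None, dialect: str = "wide"
) -> StudyDataset:
    """Read an encounter table and return a validated :class:`StudyDataset`.

    Parameters
    ----------
    path
        File path or readable text stream.
    delimiter
        ``','`` or ``'\\t'``; sniffed from the header when ``None``.
    dialect
        ``"wide"`` (one column per season, the default) or ``"long"``
        (one row per sighting with columns band_id, sex, fledge_season,
        season, code).
    """
    if hasattr(path, "read"):
        text = path.read()
    else:
        with open(path, "r", encoding="utf-8") as fh:
            text = fh.read()
    if not text.strip():
        raise ParseError("empty encounter table")
    first_line = text.splitlines()[0]
    if delimiter is None:
        delimiter = "\t" if "\t" in first_line else ","
    reader = csv.reader(io.StringIO(text), delimiter=delimiter)
    all_rows = list(reader)
    header, rows = all_rows[0], all_rows[1:]
    if dialect == "wide":
        data = _parse_wide(rows, header)
    elif dialect == "long":
        data = _parse_long(rows, header)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    data.validate()
    return data


def write_encounter_table(data: StudyDataset, path, *, delimiter: str = ",") -> None:
    """Write ``data`` in the wide format read by :func:`read_encounter_table`."""
    own = not hasattr(path, "write")
    fh = open(path, "w", encoding="utf-8", newline="") if own else path
    try:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(
            ["band_id", "sex", "fledge_season"] + [str(s) for s in data.seasons]
        )
        for ind in data.individuals:
            row = [
                ind.band_id,
                ind.sex,
                "U" if ind.fledge_season is None else str(ind.fledge_season),
            ]
            for season in data.seasons:
                if ind.entry_state == CHICK_ENTRY and season == ind.entry_season:
                    row.append("C")
                else:
                    row.append(ind.observations.get(season, ObservationCode.NOT_SEEN).value)
            writer.writerow(row)
    finally:
        if own:
            fh.close()


def summarize_dataset(data: StudyDataset) -> pd.DataFrame:
    """Per-season counts of birds seen at the colony, by status.

    Returns a frame indexed by season with columns ``pre_breeders``,
    ``breeders``, ``non_breeders``, ``total_seen``, ``breeding_pairs``
    (= breeders / 2) and ``chicks`` (the fledgling cohort banded that
    season, i.e. next season's entrants, one per successful nest in a
    fully banded colony).
    """
    idx = pd.Index(sorted(data.seasons), name="season")
    out = pd.DataFrame(
        0,
        index=idx,
        columns=[
            "pre_breeders",
            "breeders",
            "non_breeders",
            "total_seen",
            "breeding_pairs",
            "chicks",
        ],
        dtype=float,
    )
    for ind in data.individuals:
        if ind.entry_state == CHICK_ENTRY:
            out.loc[ind.entry_season, "chicks"] += 1
        for season, code in ind.observations.items():
            if code is ObservationCode.SEEN_PREBREEDER:
                out.loc[season, "pre_breeders"] += 1
            elif code in (
                ObservationCode.SEEN_BREEDER_SUCCESS,
                ObservationCode.SEEN_BREEDER_FAIL,
            ):
                out.loc[season, "breeders"] += 1
            elif code is ObservationCode.SEEN_NONBREEDER:
                out.loc[season, "non_breeders"] += 1
    out["total_seen"] = out[["pre_breeders", "breeders", "non_breeders"]].sum(axis=1)
    out["breeding_pairs"] = out["breeders"] / 2.0
    return out
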
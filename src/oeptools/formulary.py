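"""Opioid formulary: conversion factors and available formulation strengths.

Doses are compared across opioids on the oral morphine equivalent (OME)
scale: ``ome_mg = dose_mg * ome_factor(drug)``.  Oral morphine is the unit
of the scale, so its factor is exactly 1.0 by definition.  Only the oral
route is supported; parenteral and transdermal conversion are out of scope.

A versioned default conversion table (oral-route factors as published by
the US CDC, plus typical European tablet strengths) ships as package data;
see :func:`default_formulary`.  Correctness of every computation is defined
relative to the *loaded* table — nothing in the package hard-codes a factor
other than morphine's 1.0 invariant check.
"""
from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal, Mapping

from .errors import FormularyParseError, UnknownDrugError, ValidationError

Release = Literal["immediate", "extended"]

_RELEASES = ("immediate", "extended")


@dataclass(frozen=True)
class Formulation:
    """One commercially available unit: a tablet/capsule strength.

    Parameters
    ----------
    strength_mg:
        mg of drug per unit; must be positive.
    release:
        ``"immediate"`` or ``"extended"``.
    units_per_pack:
        Smallest commercial pack size, in units (>= 1).  Pack size is
        first-class data because oversized packs are a recognised barrier
        to deprescribing.
    """

    strength_mg: float
    release: Release = "immediate"
    units_per_pack: int = 10

    def __post_init__(self):
        object.__setattr__(self, "strength_mg", float(self.strength_mg))
        if not self.strength_mg > 0:
            raise ValidationError(f"strength_mg must be > 0, got {self.strength_mg}")
        if self.release not in _RELEASES:
            raise ValidationError(f"release must be one of {_RELEASES}, got {self.release!r}")
        if not (isinstance(self.units_per_pack, int) and self.units_per_pack >= 1):
            raise ValidationError(f"units_per_pack must be an integer >= 1, got {self.units_per_pack}")


@dataclass(frozen=True)
class OpioidSpec:
    """One opioid: identity, OME conversion factor, available strengths."""

    name: str
    ome_factor: float
    formulations: tuple[Formulation, ...] = ()
    is_backup_suitable: bool = False

    def __post_init__(self):
        object.__setattr__(self, "ome_factor", float(self.ome_factor))
        if not self.name or self.name != self.name.lower():
            raise ValidationError(f"opioid name must be non-empty lowercase, got {self.name!r}")
        if not self.ome_factor > 0:
            raise ValidationError(f"ome_factor must be > 0, got {self.ome_factor} for {self.name!r}")
        if self.name == "morphine" and self.ome_factor != 1.0:
            raise ValidationError("oral morphine defines the OME scale; its factor must be exactly 1.0")
        object.__setattr__(self, "formulations", tuple(self.formulations))

    @property
    def strengths_mg(self) -> tuple[float, ...]:
        return tuple(sorted({f.strength_mg for f in self.formulations}))


@dataclass
class Formulary:
    """A validated mapping of opioid name -> :class:`OpioidSpec`.

    Lookup of an unknown name raises :class:`UnknownDrugError`; there is
    deliberately no silent default.
    """

    opioids: dict[str, OpioidSpec] = field(default_factory=dict)
    version: str = "unversioned"

    def __post_init__(self):
        if not self.opioids:
            raise ValidationError("formulary must contain at least one opioid")
        for key, spec in self.opioids.items():
            if key != spec.name:
                raise ValidationError(f"formulary key {key!r} does not match opioid name {spec.name!r}")

    def __contains__(self, name: str) -> bool:
        return name in self.opioids

    def __getitem__(self, name: str) -> OpioidSpec:
        try:
            return self.opioids[name]
        except KeyError:
            raise UnknownDrugError(name) from None

    def names(self) -> tuple[str, ...]:
        return tuple(sorted(self.opioids))

    @classmethod
    def from_specs(cls, specs: Iterable[OpioidSpec], version: str = "unversioned") -> "Formulary":
        opioids: dict[str, OpioidSpec] = {}
        for spec in specs:
            if spec.name in opioids:
                raise ValidationError(f"duplicate opioid name: {spec.name!r}")
            opioids[spec.name] = spec
        return cls(opioids=opioids, version=version)


def to_ome(drug: str, dose_mg: float, formulary: Formulary) -> float:
    """Convert a drug dose (mg) to oral morphine equivalents (mg-OME).

    Exact arithmetic, no rounding: rounding to administrable tablets is the
    job of the formulation mapper, applied once at the end of the pipeline.
    """
    if dose_mg < 0:
        raise ValidationError(f"dose_mg must be >= 0, got {dose_mg}")
    return dose_mg * formulary[drug].ome_factor


def from_ome(drug: str, ome_mg: float, formulary: Formulary) -> float:
    """Convert mg-OME back to mg of ``drug`` (inverse of :func:`to_ome`)."""
    if ome_mg < 0:
        raise ValidationError(f"ome_mg must be >= 0, got {ome_mg}")
    return ome_mg / formulary[drug].ome_factor


# ---------------------------------------------------------------------------
# serialization

def _spec_to_dict(spec: OpioidSpec) -> dict:
    return {
        "name": spec.name,
        "ome_factor": spec.ome_factor,
        "formulations": [
            {"strength_mg": f.strength_mg, "release": f.release, "units_per_pack": f.units_per_pack}
            for f in spec.formulations
        ],
        "is_backup_suitable": spec.is_backup_suitable,
    }


def formulary_to_dict(formulary: Formulary) -> dict:
    return {
        "version": formulary.version,
        "opioids": [_spec_to_dict(formulary.opioids[n]) for n in formulary.names()],
    }


def _formulary_from_dict(data: Mapping) -> Formulary:
    try:
        version = str(data["version"])
        entries = data["opioids"]
    except (KeyError, TypeError) as exc:
        raise FormularyParseError(f"formulary JSON must have 'version' and 'opioids' keys: {exc}") from exc
    specs = []
    for i, entry in enumerate(entries):
        try:
            forms = tuple(
                Formulation(
                    strength_mg=float(f["strength_mg"]),
                    release=f.get("release", "immediate"),
                    units_per_pack=int(f.get("units_per_pack", 10)),
                )
                for f in entry.get("formulations", [])
            )
            specs.append(
                OpioidSpec(
                    name=entry["name"],
                    ome_factor=float(entry["ome_factor"]),
                    formulations=forms,
                    is_backup_suitable=bool(entry.get("is_backup_suitable", False)),
                )
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise FormularyParseError(f"opioid entry #{i}: {exc}") from exc
    return Formulary.from_specs(specs, version=version)


def load_formulary(path: str | Path) -> Formulary:
    """Load a formulary from JSON or CSV.

    JSON schema::

        {"version": str,
         "opioids": [{"name", "ome_factor",
                      "formulations": [{"strength_mg", "release", "units_per_pack"}],
                      "is_backup_suitable"}]}

    CSV alternative: one row per formulation with columns
    ``name, ome_factor, strength_mg, release, units_per_pack`` and an
    optional ``is_backup_suitable`` column (repeated per row).
    """
    path = Path(path)
    if path.suffix.lower() == ".csv":
        return _load_formulary_csv(path)
    with open(path) as fh:
        try:
            data = json.load(fh)
        except json.JSONDecodeError as exc:
            raise FormularyParseError(f"{path}: invalid JSON at line {exc.lineno}: {exc.msg}") from exc
    return _formulary_from_dict(data)


def _load_formulary_csv(path: Path) -> Formulary:
    rows_by_name: dict[str, list[dict]] = {}
    order: list[str] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"name", "ome_factor", "strength_mg", "release", "units_per_pack"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise FormularyParseError(f"{path}: CSV must have columns {sorted(required)}")
        for lineno, row in enumerate(reader, start=2):
            name = row["name"]
            if name not in rows_by_name:
                rows_by_name[name] = []
                order.append(name)
            elif name != order[-1] and name in order[:-1]:
                # a name that re-appears after a different name means two
                # separate blocks -> duplicate definition
                raise ValidationError(f"{path}:{lineno}: duplicate opioid name {name!r}")
            rows_by_name[name].append(row)
    specs = []
    for name in order:
        rows = rows_by_name[name]
        try:
            factors = {float(r["ome_factor"]) for r in rows}
            if len(factors) != 1:
                raise ValidationError(f"conflicting ome_factor values for {name!r}: {sorted(factors)}")
            forms = tuple(
                Formulation(
                    strength_mg=float(r["strength_mg"]),
                    release=r["release"],
                    units_per_pack=int(r["units_per_pack"]),
                )
                for r in rows
            )
            backup = any(str(r.get("is_backup_suitable", "")).lower() in ("1", "true", "yes") for r in rows)
            specs.append(OpioidSpec(name=name, ome_factor=factors.pop(), formulations=forms, is_backup_suitable=backup))
        except (KeyError, TypeError, ValueError) as exc:
            if isinstance(exc, ValidationError):
                raise
            raise FormularyParseError(f"{path}: rows for {name!r}: {exc}") from exc
    return Formulary.from_specs(specs, version=f"csv:{path.name}")


def save_formulary(formulary: Formulary, path: str | Path) -> None:
    """Write a formulary as JSON (the canonical on-disk form)."""
    with open(path, "w") as fh:
        json.dump(formulary_to_dict(formulary), fh, indent=2, sort_keys=True)
        fh.write("\n")


def default_formulary() -> Formulary:
    """The packaged oral-route conversion table with typical tablet strengths.

    Factors follow the CDC oral morphine milligram equivalent table (2016
    edition factors, oral route only; see the packaged JSON's ``version``
    field for provenance).  Methadone is deliberately absent: its
    dose-dependent, nonlinear conversion is outside this package's scope.
    """
    with resources.files("oeptools.data").joinpath("formulary_cdc_oral.json").open() as fh:
        return _formulary_from_dict(json.load(fh))
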
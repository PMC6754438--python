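"""Hypotheses table: contractile mechanisms of action and their expected effects.

Six contractile mechanism-of-action (MOA) classes are distinguished by how a
drug changes ten kinetic parameters of the simultaneously recorded action
potential (AP), cytosolic calcium transient (Ca) and contraction (Co).  The
expected effect of each MOA on each parameter is an "up", "down", "same" or a
negated expectation ("not up" etc., meaning any effect except that one is
admissible for drugs of the class).

The builtin table ships as a TSV data file so users can edit it or supply
their own hypothesis set; it is validated on load.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

from .errors import InputError

__all__ = [
    "Channel",
    "KineticParameter",
    "MOA",
    "Effect",
    "HypothesisTable",
    "builtin_table",
    "expected_effect",
    "validate_table",
    "AP_PARAMS",
    "CA_PARAMS",
    "CO_PARAMS",
]


class Channel(str, enum.Enum):
    """The three recorded transients plus the motion-artifact reference."""

    AP = "AP"
    CA = "Ca"
    CO = "Co"
    MA = "MA"


class KineticParameter(str, enum.Enum):
    """The ten per-beat kinetic parameters (4 AP + 3 Ca + 3 Co).

    Amplitudes are dimensionless ΔF/F (AP, Ca) or arbitrary motion units
    (Co); all time parameters are in milliseconds.
    """

    AP_amplitude = "AP_amplitude"
    AP_t_rise = "AP_t_rise"
    AP_t_APD = "AP_t_APD"
    AP_triangulation = "AP_triangulation"
    Ca_amplitude = "Ca_amplitude"
    Ca_t_to_peak = "Ca_t_to_peak"
    Ca_t_decay = "Ca_t_decay"
    Co_amplitude = "Co_amplitude"
    Co_t_contraction = "Co_t_contraction"
    Co_t_relaxation = "Co_t_relaxation"

    @property
    def channel(self) -> Channel:
        return Channel(self.name.split("_", 1)[0])

    @property
    def unit(self) -> str:
        if not self.name.endswith("amplitude"):
            return "ms"
        return "a.u." if self.channel is Channel.CO else "dF/F"


AP_PARAMS = tuple(p for p in KineticParameter if p.channel is Channel.AP)
CA_PARAMS = tuple(p for p in KineticParameter if p.channel is Channel.CA)
CO_PARAMS = tuple(p for p in KineticParameter if p.channel is Channel.CO)


class MOA(enum.Enum):
    """Contractile mechanism-of-action classes.

    Named after the direction of the contraction change and the pathway:
    no effect (Co=), calcium-, myosin- or cAMP-mediated increase (Co+),
    calcium-mediated or general-toxicity decrease (Co-).
    """

    Co_same = ("Co=", "aspirin")
    Co_plus_Ca = ("Co+ Ca", "ouabain")
    Co_plus_Myosin = ("Co+ myosin", "omecamtiv mecarbil")
    Co_plus_cAMP = ("Co+ cAMP", "beta-adrenergic agonist")
    Co_minus_Ca = ("Co- Ca", "verapamil")
    Co_minus_Tox = ("Co- toxicity", "doxorubicin (long term)")

    def __init__(self, label: str, typical_compound: str) -> None:
        self.label = label
        self.typical_compound = typical_compound


class Effect(str, enum.Enum):
    """Expected direction of a drug effect on one kinetic parameter.

    The three NOT members negate exactly one plain member each: "not up"
    means the drug class may leave the parameter unchanged or decrease it,
    but is not expected to increase it.
    """

    UP = "up"
    DOWN = "down"
    SAME = "same"
    NOT_UP = "not_up"
    NOT_DOWN = "not_down"
    NOT_SAME = "not_same"

    @property
    def is_negated(self) -> bool:
        return self.value.startswith("not_")

    @property
    def negates(self) -> "Effect":
        """For a NOT member, the plain effect it excludes."""
        if not self.is_negated:
            raise InputError(f"{self.name} is not a negated effect")
        return Effect(self.value[4:])

    @property
    def admissible(self) -> tuple["Effect", ...]:
        """Plain directions compatible with this expectation."""
        plain = (Effect.UP, Effect.DOWN, Effect.SAME)
        if self.is_negated:
            return tuple(e for e in plain if e is not self.negates)
        return (self,)


@dataclass(frozen=True)
class HypothesisTable:
    """Total mapping (MOA, kinetic parameter) -> expected effect."""

    cells: Mapping[tuple[MOA, KineticParameter], Effect]

    def expected_effect(self, moa: MOA, param: KineticParameter) -> Effect:
        if not isinstance(moa, MOA) or not isinstance(param, KineticParameter):
            raise InputError(f"unknown identifiers: {moa!r}, {param!r}")
        try:
            return self.cells[(moa, param)]
        except KeyError as exc:
            raise InputError(f"table has no cell for ({moa.name}, {param.name})") from exc

    def validate(self) -> list[str]:
        """Return a list of human-readable violations; empty iff the table is total."""
        violations = []
        for moa in MOA:
            for param in KineticParameter:
                cell = self.cells.get((moa, param))
                if cell is None:
                    violations.append(f"missing cell ({moa.name}, {param.name})")
                elif not isinstance(cell, Effect):
                    violations.append(
                        f"invalid effect {cell!r} at ({moa.name}, {param.name})"
                    )
        for key in self.cells:
            moa, param = key
            if not (isinstance(moa, MOA) and isinstance(param, KineticParameter)):
                violations.append(f"unknown key {key!r}")
        return violations

    def column(self, moa: MOA) -> dict[KineticParameter, Effect]:
        return {p: self.expected_effect(moa, p) for p in KineticParameter}

    # ---- serialization ----------------------------------------------------

    @classmethod
    def from_tsv(cls, path: str | Path) -> "HypothesisTable":
        """Read a table: first column parameter ids, header row MOA ids."""
        lines = Path(path).read_text().strip().splitlines()
        header = lines[0].rstrip("\n").split("\t")
        if header[0] != "parameter":
            raise InputError("first header field must be 'parameter'")
        try:
            moas = [MOA[name] for name in header[1:]]
        except KeyError as exc:
            raise InputError(f"unknown MOA column {exc}") from exc
        cells: dict[tuple[MOA, KineticParameter], Effect] = {}
        for line in lines[1:]:
            fields = line.rstrip("\n").split("\t")
            try:
                param = KineticParameter[fields[0]]
            except KeyError as exc:
                raise InputError(f"unknown kinetic parameter {fields[0]!r}") from exc
            if len(fields) != len(moas) + 1:
                raise InputError(f"row {fields[0]} has {len(fields) - 1} cells")
            for moa, token in zip(moas, fields[1:]):
                try:
                    cells[(moa, param)] = Effect(token)
                except ValueError as exc:
                    raise InputError(f"unknown effect token {token!r}") from exc
        return cls(cells)

    def to_tsv(self, path: str | Path) -> None:
        moas = list(MOA)
        rows = ["parameter\t" + "\t".join(m.name for m in moas)]
        for param in KineticParameter:
            rows.append(
                param.name
                + "\t"
                + "\t".join(self.cells[(m, param)].value for m in moas)
            )
        Path(path).write_text("\n".join(rows) + "\n")


@lru_cache(maxsize=1)
def builtin_table() -> HypothesisTable:
    """The shipped hypotheses table (validated on first load)."""
    with resources.as_file(
        resources.files("ttmkit").joinpath("data/hypothesis_table.tsv")
    ) as path:
        table = HypothesisTable.from_tsv(path)
    violations = table.validate()
    if violations:
        raise InputError(f"builtin hypothesis table invalid: {violations}")
    return table


def expected_effect(table: HypothesisTable, moa: MOA, param: KineticParameter) -> Effect:
    """Pure lookup of a table cell."""
    return table.expected_effect(moa, param)


def validate_table(table: HypothesisTable) -> list[str]:
    """Return all violations of totality/validity (empty list = valid)."""
    return table.validate()
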
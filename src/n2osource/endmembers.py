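"""Endmember signatures and the N2O-reduction line for the isotope map.

The mapping approach locates emitted N2O in the (d18O, d15N-SP) plane
relative to literature endmember boxes for bacterial denitrification
(bD), fungal denitrification (fD), nitrifier denitrification (nD) and
nitrification (Ni), and to the Rayleigh "reduction line" along which
residual N2O moves as it is partially reduced to N2.

The default table ships as an editable YAML file; because denitrifier
d18O reflects the site water, the d18O endmembers of bD, fD and nD must
be adjusted once by the measured water d18O before use (Ni oxygen comes
from atmospheric O2 and is left untouched).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, replace
from importlib import resources
from typing import Mapping, Optional

import yaml

PROCESSES = ("bD", "fD", "nD", "Ni")
#: Processes whose oxygen derives from water (d18O adjusted); Ni is not.
WATER_O_PROCESSES = ("bD", "fD", "nD")


class DoubleAdjustmentError(RuntimeError):
    """Raised when the water adjustment would be applied twice."""


@dataclass(frozen=True)
class Endmember:
    """Mean +/- SD signature of one production process (permil)."""

    sp: float
    sp_sd: float
    d18o: float
    d18o_sd: float


@dataclass(frozen=True)
class ReductionLine:
    """Net isotope effects of N2O -> N2 reduction on the residual N2O."""

    eps_sp: float
    eps_o: float
    eps_sp_sd: float = 0.0
    eps_o_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.eps_sp >= 0 or self.eps_o >= 0:
            raise ValueError("reduction epsilons must be negative (residual enrichment)")

    @property
    def slope(self) -> float:
        """dSP/d(d18O) of the reduction path (positive)."""
        return self.eps_sp / self.eps_o


@dataclass(frozen=True)
class EndmemberSet:
    """Per-process endmembers plus the state of the water adjustment."""

    members: Mapping[str, Endmember]
    water_adjusted: bool = False
    d18o_h2o: Optional[float] = None

    def __post_init__(self) -> None:
        missing = [p for p in PROCESSES if p not in self.members]
        if missing:
            raise ValueError(f"endmember table misses processes {missing}")

    def __getitem__(self, process: str) -> Endmember:
        return self.members[process]

    def adjust_for_water(self, d18o_h2o: float) -> "EndmemberSet":
        """Shift the d18O of bD, fD and nD by the water d18O, exactly once."""
        if self.water_adjusted:
            raise DoubleAdjustmentError(
                "endmember table is already water-adjusted "
                f"(d18O_H2O = {self.d18o_h2o})"
            )
        adjusted = {
            p: (replace(e, d18o=e.d18o + d18o_h2o) if p in WATER_O_PROCESSES else e)
            for p, e in self.members.items()
        }
        return EndmemberSet(adjusted, water_adjusted=True, d18o_h2o=d18o_h2o)

    @property
    def table_hash(self) -> str:
        """Short content hash identifying the table in run logs."""
        canon = ";".join(
            f"{p}:{e.sp:.6g},{e.sp_sd:.6g},{e.d18o:.6g},{e.d18o_sd:.6g}"
            for p, e in sorted(self.members.items())
        ) + f";adjusted={self.water_adjusted};h2o={self.d18o_h2o}"
        return hashlib.sha256(canon.encode()).hexdigest()[:12]


def _parse_config(cfg: dict) -> tuple[EndmemberSet, ReductionLine]:
    members = {
        p: Endmember(
            sp=float(v["sp"]), sp_sd=float(v["sp_sd"]),
            d18o=float(v["d18o"]), d18o_sd=float(v["d18o_sd"]),
        )
        for p, v in cfg["endmembers"].items()
    }
    red = cfg["reduction"]
    line = ReductionLine(
        eps_sp=float(red["eps_sp"]), eps_o=float(red["eps_o"]),
        eps_sp_sd=float(red.get("eps_sp_sd", 0.0)),
        eps_o_sd=float(red.get("eps_o_sd", 0.0)),
    )
    return EndmemberSet(members), line


def load_endmembers(path: Optional[str] = None) -> tuple[EndmemberSet, ReductionLine]:
    """Load an endmember/reduction table from YAML (default: packaged table)."""
    if path is None:
        text = (
            resources.files("n2osource").joinpath("data/endmembers.yaml").read_text()
        )
    else:
        with open(path, "r", encoding="utf-8") as fh:
            text = fh.read()
    return _parse_config(yaml.safe_load(text))


def default_endmembers() -> tuple[EndmemberSet, ReductionLine]:
    """The packaged literature default table (unadjusted) and epsilons."""
    return load_endmembers(None)
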
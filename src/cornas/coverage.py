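"""Sequencing coverage estimation from library arithmetic.

Coverage ``b`` is the fraction of the cDNA fragment population that was
actually sequenced: ``b = S / N`` with ``S`` the number of fragments
sequenced (read pairs, for paired-end runs) and ``N`` the fragment
population size before sequencing. ``N`` is rarely observed directly; it
can be reconstructed from

* the post-PCR fragment count divided by the amplification factor
  ``2**cycles`` (a standard Illumina library: 40 uL of 200 nM cDNA after
  14 PCR cycles gives 4.818e12 / 2**14 ~= 300 M pre-PCR fragments, the
  default population size used throughout), or
* the loading concentration and volume via Avogadro's number.

Imperfect PCR leaves only a fraction of the idealised fragment population:
with per-cycle efficiency ``e`` the retained fraction after ``c`` cycles is
``((1+e)/2)**c``, which reproduces the reference retention values 70%, 49%,
34% and 23% at 14 cycles for efficiencies 95%, 90%, 85% and 80%. A sample
believed sequenced at coverage S/N therefore has effective coverage
``S / (N * retention)`` when amplification was imperfect.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping

import yaml

from .errors import CoverageError, ParameterError

__all__ = [
    "DEFAULT_FRAGMENT_POPULATION",
    "DEFAULT_PCR_CYCLES",
    "DEFAULT_LOADING_VOLUME_UL",
    "AVOGADRO",
    "CoverageSpec",
    "coverage_from_reads",
    "prepcr_fragments",
    "fragments_from_concentration",
    "pcr_retention",
    "adjusted_coverage",
    "load_coverage_config",
]

#: Canonical pre-PCR cDNA fragment population size (the "300 M standard").
DEFAULT_FRAGMENT_POPULATION = 3.0e8
DEFAULT_PCR_CYCLES = 14
DEFAULT_LOADING_VOLUME_UL = 120.0
AVOGADRO = 6.022e23  # mol^-1


def coverage_from_reads(S: float, N: float) -> float:
    """Coverage b = S/N for S fragments sequenced out of a population of N."""
    if S <= 0:
        raise ParameterError(f"sequenced fragment count S must be positive, got {S}")
    if N <= 0:
        raise ParameterError(f"fragment population N must be positive, got {N}")
    if S >= N:
        raise CoverageError(
            f"S={S:g} >= N={N:g} gives coverage >= 1; the method is not "
            "recommended if the estimated coverage is more than one"
        )
    return S / N


def prepcr_fragments(post_pcr_fragments: float, cycles: int) -> float:
    """Pre-PCR fragment count: post-PCR count divided by 2**cycles.

    Assumes perfect amplification (every fragment doubles each cycle).
    """
    if post_pcr_fragments <= 0:
        raise ParameterError(
            f"post-PCR fragment count must be positive, got {post_pcr_fragments}"
        )
    if cycles < 0 or int(cycles) != cycles:
        raise ParameterError(f"PCR cycle count must be a non-negative integer, got {cycles}")
    return post_pcr_fragments / 2.0 ** cycles


def fragments_from_concentration(
    concentration_pM: float, volume_uL: float = DEFAULT_LOADING_VOLUME_UL
) -> float:
    """Fragment count from loading concentration (pM) and volume (uL).

    concentration [mol/L] x volume [L] x Avogadro. 3 pM in a standard
    120 uL loading corresponds to ~2.17e8 fragments.
    """
    if concentration_pM <= 0:
        raise ParameterError(f"concentration must be positive, got {concentration_pM}")
    if volume_uL <= 0:
        raise ParameterError(f"volume must be positive, got {volume_uL}")
    return concentration_pM * 1e-12 * volume_uL * 1e-6 * AVOGADRO


def pcr_retention(efficiency: float, cycles: int = DEFAULT_PCR_CYCLES) -> float:
    """Fraction of the perfect-amplification population retained.

    With per-cycle amplification efficiency ``e`` (probability that a
    fragment is duplicated in a cycle), the population grows by (1+e) per
    cycle instead of 2, so after ``c`` cycles only ``((1+e)/2)**c`` of the
    idealised population is present.
    """
    if not (0.0 < efficiency <= 1.0):
        raise ParameterError(f"PCR efficiency must be in (0, 1], got {efficiency}")
    if cycles < 0 or int(cycles) != cycles:
        raise ParameterError(f"PCR cycle count must be a non-negative integer, got {cycles}")
    return ((1.0 + efficiency) / 2.0) ** cycles


def adjusted_coverage(
    S: float,
    N: float,
    efficiency: float = 1.0,
    cycles: int = DEFAULT_PCR_CYCLES,
) -> float:
    """Coverage S / (N x retention): the effective coverage when PCR was
    imperfect and the nominal population N overstates what was present.

    Raises :class:`CoverageError` when the adjusted coverage reaches 1.
    """
    if S <= 0 or N <= 0:
        raise ParameterError("S and N must be positive")
    retention = pcr_retention(efficiency, cycles)
    b = S / (N * retention)
    if b >= 1.0:
        raise CoverageError(
            f"adjusted coverage {b:.3f} >= 1 (S={S:g}, N={N:g}, "
            f"efficiency={efficiency}, cycles={cycles}); the method is not "
            "recommended if the estimated coverage is more than one"
        )
    return b


@dataclass(frozen=True)
class CoverageSpec:
    """Per-sample coverage and the quantities it was derived from."""

    sample_id: str
    coverage_b: float
    reads_S: float | None = None
    fragments_N: float | None = None
    pcr_cycles: int = DEFAULT_PCR_CYCLES
    pcr_efficiency: float = 1.0

    def __post_init__(self):
        if not (0.0 < self.coverage_b < 1.0):
            raise CoverageError(
                f"sample {self.sample_id!r}: coverage {self.coverage_b!r} outside (0, 1)"
            )

    @classmethod
    def from_config(cls, sample_id: str, entry: Mapping[str, Any]) -> "CoverageSpec":
        """Build a spec from one config entry.

        Accepted keys: either ``coverage`` directly, or ``total_reads``
        with ``end_mode`` ('single' or 'paired'; paired-end reads come in
        pairs per fragment, so S = total_reads / 2) plus one way of fixing
        the fragment population:

        * ``fragments_N`` — given directly;
        * ``concentration_pM`` (+ optional ``volume_uL``, default 120);
        * ``post_pcr_fragments`` (+ ``pcr_cycles``, default 14);
        * nothing — the 300 M standard population.

        ``total_reads`` may be a list (multiple sequencing runs of one
        sample); runs are averaged before computing coverage. Optional
        ``pcr_efficiency`` (default 1.0) rescales the population for
        imperfect amplification.
        """
        entry = dict(entry)
        efficiency = float(entry.get("pcr_efficiency", 1.0))
        cycles = int(entry.get("pcr_cycles", DEFAULT_PCR_CYCLES))

        if "coverage" in entry:
            return cls(
                sample_id=sample_id,
                coverage_b=float(entry["coverage"]),
                pcr_cycles=cycles,
                pcr_efficiency=efficiency,
            )

        if "total_reads" not in entry:
            raise ParameterError(
                f"sample {sample_id!r}: config must provide either 'coverage' "
                "or 'total_reads'"
            )
        total_reads = entry["total_reads"]
        if isinstance(total_reads, (list, tuple)):
            total_reads = sum(float(r) for r in total_reads) / len(total_reads)
        total_reads = float(total_reads)
        end_mode = entry.get("end_mode", "single")
        if end_mode not in ("single", "paired"):
            raise ParameterError(
                f"sample {sample_id!r}: end_mode must be 'single' or 'paired', "
                f"got {end_mode!r}"
            )
        S = total_reads / 2.0 if end_mode == "paired" else total_reads

        if "fragments_N" in entry:
            N = float(entry["fragments_N"])
        elif "concentration_pM" in entry:
            N = fragments_from_concentration(
                float(entry["concentration_pM"]),
                float(entry.get("volume_uL", DEFAULT_LOADING_VOLUME_UL)),
            )
        elif "post_pcr_fragments" in entry:
            N = prepcr_fragments(float(entry["post_pcr_fragments"]), cycles)
        else:
            N = DEFAULT_FRAGMENT_POPULATION

        b = adjusted_coverage(S, N, efficiency, cycles)
        return cls(
            sample_id=sample_id,
            coverage_b=b,
            reads_S=S,
            fragments_N=N,
            pcr_cycles=cycles,
            pcr_efficiency=efficiency,
        )


def load_coverage_config(path: str | Path) -> dict[str, CoverageSpec]:
    """Read a YAML coverage config: a mapping of sample_id -> entry.

    See :meth:`CoverageSpec.from_config` for the entry schema.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, Mapping) or not raw:
        raise ParameterError(
            f"coverage config {path}: expected a non-empty mapping of "
            "sample_id -> settings"
        )
    return {
        str(sid): CoverageSpec.from_config(str(sid), entry) for sid, entry in raw.items()
    }
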
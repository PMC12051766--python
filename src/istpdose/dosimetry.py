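"""Absorbed dose from organ TIAs via the MIRD S-value formalism.

The absorbed dose to a target region is the sum over source regions of the
source TIA times the S-value S(target <- source), the absorbed dose per unit
cumulated activity.  S-values here are stored in Gy per MBq*h so the product
with TIA in MBq*h yields Gy directly; the file header must declare this unit
and the reader validates the declaration, guarding against silent
Bq*s-vs-MBq*h factor errors.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .kinetics import ORGANS

#: The one supported S-value unit (dose per unit cumulated activity).
SVALUE_UNITS = "Gy_per_MBq_h"


class SValueSchemaError(ValueError):
    """The S-value file violates the documented schema."""


@dataclass(frozen=True)
class SValueMatrix:
    """Source->target absorbed-dose-per-unit-TIA factors.

    ``entries`` maps (source, target) to an S-value in Gy/(MBq*h).  Every
    target must have a self-dose entry; the matrix need not be symmetric.
    """

    entries: dict[tuple[str, str], float]
    provenance: str = "unspecified"

    def __post_init__(self) -> None:
        organs = self.organs
        for (src, tgt), s in self.entries.items():
            if s < 0:
                raise SValueSchemaError(f"negative S-value for ({src}->{tgt}): {s}")
        for organ in organs:
            if (organ, organ) not in self.entries:
                raise SValueSchemaError(f"missing self-dose entry for {organ!r}")

    @property
    def organs(self) -> tuple[str, ...]:
        seen: list[str] = []
        for src, tgt in self.entries:
            for o in (src, tgt):
                if o not in seen:
                    seen.append(o)
        return tuple(sorted(seen))

    def s(self, target: str, source: str) -> float:
        """S(target <- source); KeyError if absent."""
        return self.entries[(source, target)]

    def to_csv(self, path: str | Path) -> None:
        rows = [
            {"source": src, "target": tgt, "s_value": s, "units": SVALUE_UNITS}
            for (src, tgt), s in sorted(self.entries.items())
        ]
        pd.DataFrame(rows).to_csv(path, index=False)


def read_svalue_matrix(path: str | Path, known_organs: tuple[str, ...] = ORGANS) -> SValueMatrix:
    """Read and validate an S-value CSV with columns (source, target, s_value, units).

    Unknown organ names and unit declarations other than Gy_per_MBq_h are
    rejected; validation of self-dose entries and non-negativity happens in
    the :class:`SValueMatrix` constructor.
    """
    df = pd.read_csv(path, comment="#")
    required = {"source", "target", "s_value", "units"}
    if not required.issubset(df.columns):
        raise SValueSchemaError(
            f"S-value file must have columns {sorted(required)}, got {list(df.columns)}"
        )
    bad_units = set(df["units"].unique()) - {SVALUE_UNITS}
    if bad_units:
        raise SValueSchemaError(
            f"unsupported S-value units {sorted(bad_units)}; expected {SVALUE_UNITS!r}"
        )
    entries: dict[tuple[str, str], float] = {}
    for r in df.itertuples():
        src, tgt = str(r.source), str(r.target)
        for organ in (src, tgt):
            if organ not in known_organs:
                raise SValueSchemaError(
                    f"unknown organ {organ!r} in S-value file; expected {known_organs}"
                )
        if (src, tgt) in entries:
            raise SValueSchemaError(f"duplicate entry for ({src}->{tgt})")
        entries[(src, tgt)] = float(r.s_value)
    return SValueMatrix(entries=entries, provenance=str(path))


def default_svalue_fixture() -> SValueMatrix:
    """The synthetic 4-organ S-value fixture shipped with the package."""
    return read_svalue_matrix(Path(__file__).parent / "data" / "svalues_synthetic.csv")


def absorbed_dose(
    tia_by_source: dict[str, float],
    svalues: SValueMatrix,
    target: str,
    *,
    allow_missing_cross: bool = False,
) -> float:
    """Absorbed dose D(target) = sum_source TIA_source * S(target <- source), Gy.

    Every source must have an S-value toward the target unless
    ``allow_missing_cross`` treats absent cross-terms (source != target) as
    zero.
    """
    dose = 0.0
    for source, tia in tia_by_source.items():
        try:
            s = svalues.s(target, source)
        except KeyError:
            if allow_missing_cross and source != target:
                continue
            raise SValueSchemaError(
                f"no S-value for ({source}->{target}); "
                "set allow_missing_cross=True to treat cross-terms as zero"
            ) from None
        dose += tia * s
    return dose


def dose_table(
    tia_table: pd.DataFrame,
    svalues: SValueMatrix,
    *,
    allow_missing_cross: bool = False,
) -> pd.DataFrame:
    """Per-(patient, cycle) doses for every target organ.

    ``tia_table`` needs columns (patient_id, cycle, organ, tia_MBq_h); organs
    missing for a cycle simply contribute nothing (their TIA is unknown, not
    zero — the self-dose term dominates by orders of magnitude here).
    """
    rows = []
    for (pid, cyc), grp in tia_table.groupby(["patient_id", "cycle"], sort=True):
        tia_by_source = dict(zip(grp["organ"], grp["tia_MBq_h"]))
        for target in grp["organ"]:
            rows.append(
                {
                    "patient_id": pid,
                    "cycle": cyc,
                    "organ": target,
                    "dose_Gy": absorbed_dose(
                        tia_by_source,
                        svalues,
                        target,
                        allow_missing_cross=allow_missing_cross,
                    ),
                }
            )
    return pd.DataFrame(rows, columns=["patient_id", "cycle", "organ", "dose_Gy"])
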
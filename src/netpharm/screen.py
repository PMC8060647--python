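"""Pharmacokinetic compound screening and target collection.

The screen keeps a herb ingredient as bioactive when its oral bioavailability
is at least 30% AND it is either drug-like (DL >= 0.18) or well-scored by its
source database (score >= 20). All thresholds are inclusive and configurable.
A record without a database score is judged on drug-likeness alone.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

from .records import CompoundRecord, GeneSet, TargetAssociation

__all__ = ["screen_compounds", "collect_targets", "convert_dose_human_to_rat"]

logger = logging.getLogger(__name__)

#: Human body mass (kg) and human:rat surface-area factor folded into the
#: standard body-surface-area dose conversion DB(rat) = DA(human) * 7 / 388.
DOSE_FACTOR_NUM = 7.0
DOSE_FACTOR_DEN = 388.0


def passes_screen(
    record: CompoundRecord,
    ob_min: float = 30.0,
    dl_min: float = 0.18,
    score_min: float = 20.0,
) -> bool:
    """Inclusive-threshold screen predicate for a single record."""
    if record.OB < ob_min:
        return False
    if record.DL >= dl_min:
        return True
    return record.score is not None and record.score >= score_min


def screen_compounds(
    table: Sequence[CompoundRecord],
    ob_min: float = 30.0,
    dl_min: float = 0.18,
    score_min: float = 20.0,
) -> list[CompoundRecord]:
    """Return the records passing OB >= ob_min AND (DL >= dl_min OR score >= score_min).

    Input order is preserved; screening is idempotent and raising any
    threshold can only shrink the output.
    """
    for name, thr in (("ob_min", ob_min), ("dl_min", dl_min), ("score_min", score_min)):
        if thr < 0:
            raise ValueError(f"{name} must be nonnegative, got {thr!r}")
    ids = [r.compound_id for r in table]
    if len(set(ids)) != len(ids):
        raise ValueError("compound_id values must be unique within a table")
    return [r for r in table if passes_screen(r, ob_min, dl_min, score_min)]


def collect_targets(
    screened: Sequence[CompoundRecord],
    associations: Iterable[TargetAssociation],
) -> GeneSet:
    """Nonredundant target genes of the screened compounds.

    Association pairs whose compound_id is absent from ``screened`` are
    ignored (one aggregate warning is logged); the result is the
    deduplicated, deterministically sorted union of the remaining genes.
    """
    keep = {r.compound_id for r in screened}
    genes: set[str] = set()
    n_ignored = 0
    for a in associations:
        if a.compound_id in keep:
            genes.add(a.gene)
        else:
            n_ignored += 1
    if n_ignored:
        logger.warning(
            "collect_targets: ignored %d association pair(s) referencing "
            "compounds outside the screened set",
            n_ignored,
        )
    return GeneSet(name="drug-targets", genes=frozenset(genes), provenance=("screen",))


def convert_dose_human_to_rat(human_dose: float) -> float:
    """Convert a human daily dose to the equivalent rat dose (per kg).

    Uses the body-surface-area conversion DB(rat) = DA(human) * 7 / 388, the
    standard human-to-rat scaling for a 70 kg adult. Units follow the input:
    a dose in g/day yields g/kg/day on the rat side.
    """
    if human_dose < 0:
        raise ValueError(f"human_dose must be nonnegative, got {human_dose!r}")
    return human_dose * DOSE_FACTOR_NUM / DOSE_FACTOR_DEN
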
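"""Semi-theoretic estimate of the genome fraction coding for CRMs.

A pure, auditable arithmetic chain. Starting from the observed CRMC
coverage of the peak-covered genome regions, it corrects for expected
false positives (count x mean length over the genome length) and false
negatives (an FNR applied to the corrected fraction), extrapolates into
the peak-uncovered regions via the relative CRMC position density implied
by proportions of selective neutrality (phyloP score in [-1, 1]), and
converts the resulting genome fractions into expected element counts using
mean CRM and TFBS-island lengths.

Two output modes are produced side by side: ``full`` carries every
intermediate at full precision; ``printed`` rounds each intermediate at
the conventional reporting checkpoints (percentages to 2 decimals, the FP
fraction ceiled at 3 decimals of a percent) so that downstream numbers
reproduce a report whose intermediates were themselves rounded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import pandas as pd

__all__ = ["BudgetInputs", "BudgetEstimates", "density_ratio", "budget"]


def density_ratio(pc: float, pu: float, pn: float) -> float:
    """Relative CRMC position density, uncovered vs covered regions.

    ``pc``, ``pu``, ``pn`` are the proportions of neutrality of the
    peak-covered, peak-uncovered and non-CRMC positions. The non-neutral
    excess of each region over the non-CRMC baseline is attributed to CRMC
    positions, so the density ratio is

        ((1 - pu) - (1 - pn)) / ((1 - pc) - (1 - pn)).
    """
    denom = (1.0 - pc) - (1.0 - pn)
    if denom == 0:
        raise ZeroDivisionError("pc == pn: covered regions show no excess constraint")
    return ((1.0 - pu) - (1.0 - pn)) / denom


@dataclass(frozen=True)
class BudgetInputs:
    """Scalar inputs of the budget chain; fractions are genome fractions.

    ``uncovered_fraction`` defaults to 1 - covered_fraction but is an
    independent field so a report's printed arithmetic can be reproduced
    verbatim. FP input is accepted either as (count, mean length) or
    directly as a genome fraction (``fp_fraction``).
    """

    genome_length: float = 2_725_521_370.0
    covered_fraction: float = 0.799
    crmc_fraction: float = 0.555
    non_crmc_fraction: float = 0.244
    tfbs_fraction_of_crm: float = 0.429
    neutrality_covered: float = 0.78
    neutrality_uncovered: float = 0.83
    neutrality_noncrmc: float = 0.89
    expected_fp_count: float = 1486.0
    fp_mean_length: float = 64.0
    fp_fraction: float | None = None
    fnr: float = 0.007
    mean_crm_length: float = 1893.0
    mean_island_length: float = 17.0
    uncovered_fraction: float | None = None

    def __post_init__(self):
        for name in ("covered_fraction", "crmc_fraction", "non_crmc_fraction",
                     "tfbs_fraction_of_crm", "neutrality_covered",
                     "neutrality_uncovered", "neutrality_noncrmc", "fnr"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.fnr >= 1.0:
            raise ValueError("fnr must be < 1")

    @property
    def uncovered(self) -> float:
        if self.uncovered_fraction is not None:
            return self.uncovered_fraction
        return 1.0 - self.covered_fraction

    @property
    def fp_genome_fraction(self) -> float:
        if self.fp_fraction is not None:
            return self.fp_fraction
        return self.expected_fp_count * self.fp_mean_length / self.genome_length


@dataclass(frozen=True)
class BudgetEstimates:
    """All quantities as genome fractions in percent, except counts/ratios."""

    density_ratio: float  # uncovered/covered CRMC density, fraction
    fp_fraction: float  # % of genome
    true_crmc_fraction: float  # % of genome
    fn_fraction: float  # % of genome
    for_noncrmc: float  # false omission rate among non-CRMC positions, %
    true_covered_crm_fraction: float  # % of genome
    uncovered_crm_fraction: float  # % of genome
    total_crm_fraction: float  # % of genome
    predicted_share: float  # covered true CRMs / total, %
    tfbs_genome_fraction: float  # % of genome
    n_crms: float
    n_islands: float

    def to_series(self) -> pd.Series:
        return pd.Series(asdict(self))


def _ceil_at(x: float, decimals: int) -> float:
    scale = 10 ** decimals
    return math.ceil(x * scale - 1e-12) / scale


def budget(inputs: BudgetInputs, mode: str = "full") -> BudgetEstimates:
    """Run the budget chain; ``mode`` is ``"full"`` or ``"printed"``.

    In printed mode each checkpoint is rounded the way a report prints it
    (percentages to 2 decimals; the FP percent ceiled at 3 decimals; the
    density ratio to 4 decimals of a fraction) before it feeds the next
    step, so the chain reproduces reported values exactly.
    """
    printed = {"full": False, "printed": True}[mode]

    def chk(x: float, decimals: int = 2) -> float:
        return round(x, decimals) if printed else x

    fp_pct = inputs.fp_genome_fraction * 100.0
    if printed:
        fp_pct = _ceil_at(fp_pct, 3)
    true_crmc_pct = chk(inputs.crmc_fraction * 100.0 - fp_pct, 3)
    fn_pct = chk(inputs.fnr * (true_crmc_pct / 100.0) / (1.0 - inputs.fnr) * 100.0)
    for_pct = chk(fn_pct / (inputs.non_crmc_fraction * 100.0) * 100.0)
    true_covered_pct = chk(inputs.crmc_fraction * 100.0 - fp_pct + fn_pct)
    ratio = density_ratio(
        inputs.neutrality_covered, inputs.neutrality_uncovered, inputs.neutrality_noncrmc
    )
    if printed:
        ratio = round(ratio, 4)
    uncovered_pct = chk(
        inputs.uncovered * (true_covered_pct / 100.0) * ratio
        / inputs.covered_fraction * 100.0
    )
    total_pct = chk(true_covered_pct + uncovered_pct)
    predicted_share = chk(true_covered_pct / total_pct * 100.0)
    tfbs_pct = chk(inputs.tfbs_fraction_of_crm * total_pct)
    n_crms = inputs.genome_length * (total_pct / 100.0) / inputs.mean_crm_length
    n_islands = inputs.genome_length * (tfbs_pct / 100.0) / inputs.mean_island_length
    if printed:
        n_crms, n_islands = round(n_crms), round(n_islands)
    return BudgetEstimates(
        density_ratio=ratio,
        fp_fraction=fp_pct,
        true_crmc_fraction=true_crmc_pct,
        fn_fraction=fn_pct,
        for_noncrmc=for_pct,
        true_covered_crm_fraction=true_covered_pct,
        uncovered_crm_fraction=uncovered_pct,
        total_crm_fraction=total_pct,
        predicted_share=predicted_share,
        tfbs_genome_fraction=tfbs_pct,
        n_crms=n_crms,
        n_islands=n_islands,
    )


def report(inputs: BudgetInputs) -> pd.DataFrame:
    """Side-by-side full-precision and printed-rounding estimates."""
    full = budget(inputs, "full").to_series()
    printed = budget(inputs, "printed").to_series()
    return pd.DataFrame({"full_precision": full, "printed_rounding": printed})
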
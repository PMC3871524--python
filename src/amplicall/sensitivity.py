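"""Assay-design calculators and the dilution-series experiment.

Covers the arithmetic that sizes the assay: the read depth needed for a
target allele fraction under the k-supporting-read rule (10 reads at 1%
means at least 1,000 total reads; 0.1% needs 10,000), the exact binomial
probability of reaching the read threshold at a given depth, the DNA-mass
to cell-equivalent conversion (7 pg per diploid cell), the dideoxy
(Sanger) detectability model (~20% mutated alleles, i.e. ~40% tumor cells
for a heterozygous mutation at a dysomic locus), and an end-to-end
dilution-series runner that measures the pipeline's analytical
sensitivity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import refdata
from .call import CallCriteria, process_reads
from .demux import design_grid
from .refdata import Q787Q_SITE_CDS, VariantKey
from .simulate import SampleSpec, SimConfig, VariantSpec, simulate_reads

__all__ = [
    "LODResult",
    "SangerModel",
    "min_depth",
    "detection_probability",
    "lod_table",
    "dna_to_cell_equivalents",
    "sanger_detectable",
    "run_dilution_experiment",
    "DilutionOutcome",
]

PG_PER_DIPLOID_CELL = 7.0


@dataclass(frozen=True)
class LODResult:
    """Depth requirement and detection probability at one allele fraction."""

    allele_fraction: float
    min_reads_required: int
    detection_probability: float


@dataclass(frozen=True)
class SangerModel:
    """Analytical-sensitivity floor of dideoxy sequencing.

    ``allele_fraction_threshold`` is the conventional ~20% mutated-allele
    floor; under the heterozygous/dysomic assumption this corresponds to a
    tumor-cell proportion of twice the allele threshold (40%).
    """

    allele_fraction_threshold: float = 0.20

    @property
    def purity_threshold(self) -> float:
        return 2.0 * self.allele_fraction_threshold


def min_depth(allele_fraction: float, min_count: int = 10) -> int:
    """Smallest total read depth whose expected variant-read count reaches
    ``min_count``: ceil(min_count / allele_fraction)."""
    if not 0.0 < allele_fraction <= 1.0:
        raise ValueError("allele_fraction must be in (0, 1]")
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    depth = math.ceil(min_count / allele_fraction)
    # guard against float-ceiling artifacts at exact multiples
    while depth > 1 and (depth - 1) * allele_fraction >= min_count:
        depth -= 1
    while depth * allele_fraction < min_count:
        depth += 1
    return depth


def detection_probability(depth: int, allele_fraction: float, min_count: int = 10) -> float:
    """P(Binomial(depth, allele_fraction) >= min_count)."""
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if not 0.0 <= allele_fraction <= 1.0:
        raise ValueError("allele_fraction must be in [0, 1]")
    if min_count < 0:
        raise ValueError("min_count must be >= 0")
    if min_count == 0:
        return 1.0
    return float(stats.binom.sf(min_count - 1, depth, allele_fraction))


def lod_table(
    fractions: Sequence[float],
    min_count: int = 10,
    depth: int | None = None,
) -> list[LODResult]:
    """Depth requirements (and, at ``depth``, detection probabilities) for a
    set of allele fractions."""
    out = []
    for f in fractions:
        req = min_depth(f, min_count)
        prob = detection_probability(depth if depth is not None else req, f, min_count)
        out.append(LODResult(f, req, prob))
    return out


def dna_to_cell_equivalents(mass_ng: float, pg_per_cell: float = PG_PER_DIPLOID_CELL) -> float:
    """Diploid-cell equivalents in a DNA mass (7 pg per cell): 2 ng is
    ~285.7 cells' DNA."""
    if mass_ng <= 0:
        raise ValueError("mass must be positive")
    if pg_per_cell <= 0:
        raise ValueError("pg_per_cell must be positive")
    return 1000.0 * mass_ng / pg_per_cell


def sanger_detectable(allele_fraction: float, model: SangerModel = SangerModel()) -> bool:
    """True when the mutated-allele fraction reaches the dideoxy floor."""
    if not 0.0 <= allele_fraction <= 1.0:
        raise ValueError("allele_fraction must be in [0, 1]")
    return allele_fraction >= model.allele_fraction_threshold


# --------------------------------------------------------------------------
# dilution-series experiment

@dataclass(frozen=True)
class DilutionOutcome:
    table: pd.DataFrame
    analytical_sensitivity_fraction: float | None

    @property
    def analytical_sensitivity_percent(self) -> float | None:
        f = self.analytical_sensitivity_fraction
        return None if f is None else 100.0 * f


def run_dilution_experiment(
    dilutions: Sequence[int] = (1, 2, 10, 100, 1000),
    depth: int = 700,
    replicates: int = 2,
    criteria: CallCriteria = CallCriteria(),
    seed: int = 0,
    amplicons=None,
    **sim_kwargs,
) -> DilutionOutcome:
    """Measure the pipeline's analytical sensitivity on a dilution series.

    A homozygous carrier of the synonymous exon 20 polymorphism (G>A at the
    third base of codon 787) is serially diluted 1:N into wild-type DNA
    (allele fraction 1/N); each dilution is simulated ``replicates`` times
    at ``depth`` reads on the exon 20 target and run through the full
    demultiplex -> align -> call pipeline.  The analytical sensitivity is
    the smallest fraction called positive in >= 95% of replicates.

    Extra keyword arguments are forwarded to :class:`SimConfig` (error
    rates, strand balance, ...).
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if amplicons is None:
        amplicons = refdata.load_amplicons()
    exon20 = [a for a in amplicons if a.exon_id == 20]
    if not exon20:
        raise ValueError("exon 20 amplicon required for the dilution experiment")
    grid = design_grid(1, refdata.DEFAULT_MID_INVENTORY, sample_ids=("DIL",), exons=(20,))
    target_key = refdata.normalize_variant(
        exon20[0],
        VariantKey(Q787Q_SITE_CDS, Q787Q_SITE_CDS,
                   exon20[0].base_at_cds(Q787Q_SITE_CDS), "A"),
    )
    seed_seq = np.random.SeedSequence(seed)
    rows = []
    for dilution in dilutions:
        fraction = 1.0 / dilution
        called = 0
        support = []
        for child in seed_seq.spawn(replicates):
            rep_seed = int(child.generate_state(1)[0] % (2**31))
            spec = VariantSpec(
                exon_id=20, kind="snv",
                cds_start=Q787Q_SITE_CDS, cds_end=Q787Q_SITE_CDS,
                alt="A", allele_fraction=fraction,
            )
            config = SimConfig(
                samples=(SampleSpec("DIL", (spec,)),),
                depth_per_target=depth,
                seed=rep_seed,
                **sim_kwargs,
            )
            reads, _ = simulate_reads(config, grid, exon20)
            calls_by_target, _ = process_reads(reads, grid, exon20, criteria)
            hit = next(
                (c for c in calls_by_target[("DIL", 20)] if c.variant_key == target_key),
                None,
            )
            if hit is not None and hit.called:
                called += 1
            support.append(hit.tally.support if hit is not None else 0)
        rows.append(
            dict(
                dilution=f"1:{dilution}",
                allele_fraction=fraction,
                replicates=replicates,
                call_rate=called / replicates,
                mean_variant_reads=float(np.mean(support)),
                depth=depth,
            )
        )
    table = pd.DataFrame(rows)
    consistent = table[table["call_rate"] >= 0.95]
    sens = float(consistent["allele_fraction"].min()) if len(consistent) else None
    return DilutionOutcome(table=table, analytical_sensitivity_fraction=sens)
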
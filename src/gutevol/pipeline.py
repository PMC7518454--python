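"""End-to-end orchestration of one sample: QC, partitioning, multi-run
alignment, consensus polymorphism calling, IS detection and annotation.

The three alignment runs emulate the study's three independent mappers with
three parameterizations of the built-in aligner (seed lengths 17/21/25).
SNP/indel calls come from the filtered-pileup caller on the first two runs
and the polymorphism-mode caller on the third; the consensus rule (>= 2
runs, mean frequency over all three >= 5%) then applies, after masking
repeats and +-10 bp around structural junctions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .genome import AnnotatedGenome
from .simulate import ReadPair
from .qc import QCParams, qc_pairs, partition_reads
from .align import Aligner, AlignmentRecord, build_pileup, sort_records
from .variants import (ConsensusVariant, MaskSet, MutationRecord, apply_mask,
                       annotate_variant, call_naive, call_polymode,
                       merge_runs)
from .mge import ISCall, detect_breakpoints, find_is_insertions

SEED_LENGTHS = (17, 21, 25)


@dataclass
class SampleResult:
    sample: str
    consensus: list[ConsensusVariant]
    is_calls: list[ISCall]
    records: list[MutationRecord]
    mask: MaskSet
    alignments: dict[str, list[AlignmentRecord]] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"mouse": r.mouse, "cohort": r.cohort, "position": r.position,
                 "mutation": r.mutation, "gene": r.gene,
                 "annotation": r.annotation, "frequency": r.frequency}
                for r in self.records]
        return pd.DataFrame(rows, columns=["mouse", "cohort", "position",
                                           "mutation", "gene", "annotation",
                                           "frequency"])


def call_sample(pairs: list[ReadPair], invader: AnnotatedGenome,
                resident: AnnotatedGenome | None = None,
                sample: str = "sample", cohort: str = "",
                qc_params: QCParams | None = None,
                seed_lengths: tuple[int, ...] = SEED_LENGTHS,
                fragment_mean: float = 500, fragment_sd: float = 60,
                min_mean_freq: float = 0.05,
                keep_alignments: bool = False) -> SampleResult:
    """Run the whole per-sample pipeline on raw read pairs."""
    kept = qc_pairs(pairs, qc_params or QCParams())
    if resident is not None:
        kept = partition_reads(kept, invader, resident).bins["invader"]

    run_records: dict[str, list[AlignmentRecord]] = {}
    for s in seed_lengths:
        aligner = Aligner(invader, seed_length=s)
        run_records[f"seed{s}"] = sort_records(aligner.align_pairs(kept))

    labels = list(run_records)
    mid = labels[min(1, len(labels) - 1)]
    is_calls = find_is_insertions(run_records[mid], invader,
                                  fragment_mean=fragment_mean,
                                  fragment_sd=fragment_sd)
    junctions = [c.site for c in is_calls]
    junctions += detect_breakpoints(run_records[mid])
    mask = MaskSet.from_genome(invader, junctions=junctions)

    run_calls = []
    for i, label in enumerate(labels):
        pileup = build_pileup(run_records[label], invader)
        if i < len(labels) - 1:
            calls = call_naive(pileup, run=label)
        else:
            calls = call_polymode(pileup, run=label)
        run_calls.append(apply_mask(calls, mask))
    consensus = merge_runs(run_calls, n_runs_total=len(labels),
                           min_mean_freq=min_mean_freq, genome=invader)

    records = [annotate_variant(v, invader, mouse=sample, cohort=cohort)
               for v in consensus]
    records += [annotate_variant(c, invader, mouse=sample, cohort=cohort)
                for c in is_calls]
    result = SampleResult(sample, consensus, is_calls, records, mask)
    if keep_alignments:
        result.alignments = run_records
    return result
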
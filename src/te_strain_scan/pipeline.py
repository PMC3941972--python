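"""End-to-end orchestration of the screen and characterization stages.

`run_screen` composes qc -> assign -> enrich -> profile and nominates
candidate families: strongly enriched in one strain (fold ratio and
chi-squared), with an active-like (homogeneous) read population in
exactly one strain.  `run_characterize` takes one candidate through
copy extraction, core consensus, TIR/ORF annotation, fragment
collection and age dating, plus the expression ANOVA when count data
are supplied.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from . import annotation as ann
from . import enrichment as enr
from . import expression as expr
from . import phylo
from . import site_profile as sp
from .io import FastqRead
from .qc import QCParams, QCSummary, qc_pipeline


@dataclass
class RunManifest:
    seed: int | None = None
    stages: list[dict] = field(default_factory=list)

    def record(self, stage: str, params: dict, payload: str = "") -> None:
        digest = hashlib.sha256(payload.encode()).hexdigest()[:16]
        self.stages.append({"stage": stage, "params": params,
                            "checksum": digest})

    def to_json(self) -> str:
        return json.dumps({"seed": self.seed, "stages": self.stages},
                          indent=2, default=str)


@dataclass
class ScreenResult:
    enrichment: pd.DataFrame
    profiles: dict[str, dict[str, sp.SiteProfile]]  # family -> strain -> prof
    activity: pd.DataFrame
    candidates: list[str]
    qc_summaries: dict[str, QCSummary]
    manifest: RunManifest


def run_screen(
    library: enr.RepeatLibrary,
    reads_by_strain: Mapping[str, Iterable[FastqRead]],
    strain_pair: tuple[str, str],
    denominators: Mapping[str, int] | None = None,
    qc_params: QCParams | None = None,
    k: int = enr.DEFAULT_K,
    min_identity: float = enr.DEFAULT_MIN_IDENTITY,
    min_aligned_fraction: float = enr.DEFAULT_MIN_ALIGNED_FRACTION,
    fold_threshold: float = 10.0,
    p_threshold: float = 1e-3,
    h_threshold: float = sp.DEFAULT_H_THRESHOLD,
    min_depth: int = sp.DEFAULT_MIN_DEPTH,
    seed: int | None = None,
) -> ScreenResult:
    """qc -> assign -> enrich -> profile; returns report + candidates.

    When `denominators` (reads mapped to the host genome per strain) is
    omitted, total QC-surviving reads are used instead and the report is
    flagged accordingly.
    """
    manifest = RunManifest(seed=seed)
    qc_params = qc_params or QCParams()
    index = enr.build_index(library, k)
    assignments: dict[str, list[enr.ReadAssignment]] = {}
    survivors: dict[str, int] = {}
    qc_summaries: dict[str, QCSummary] = {}
    for strain, reads in reads_by_strain.items():
        summary = QCSummary()
        clean = list(qc_pipeline(reads, qc_params, summary))
        qc_summaries[strain] = summary
        survivors[strain] = summary.n_surviving
        assignments[strain] = enr.assign_reads(
            clean, index, min_identity, min_aligned_fraction)
    manifest.record("qc+assign", {"k": k, "min_identity": min_identity},
                    str({s: len(a) for s, a in assignments.items()}))

    if denominators is None:
        denominators = survivors
        denominator_source = "total QC-surviving reads (substituted for genome-mapped)"
    else:
        denominator_source = "genome-mapped"
    table = enr.count_table(assignments, denominators,
                            families=list(library.entries),
                            denominator_source=denominator_source)
    report = enr.enrichment_report(table, strain_pair)
    manifest.record("enrich", {"denominator_source": denominator_source},
                    report.to_csv())

    profiles: dict[str, dict[str, sp.SiteProfile]] = {}
    activity_rows = []
    for fam, cons in library.entries.items():
        per_strain = {}
        for strain in assignments:
            fam_assign = [a for a in assignments[strain]
                          if a.family_id == fam]
            per_strain[strain] = sp.pileup(
                fam_assign, len(cons), fam,
                mapped_denominator=denominators[strain],
                min_depth=min_depth)
        profiles[fam] = per_strain
        activity_rows.append(sp.activity_summary(per_strain, h_threshold))
    activity = pd.concat(activity_rows, ignore_index=True)
    manifest.record("profile", {"min_depth": min_depth, "h_threshold": h_threshold},
                    activity.to_csv())

    s1, s2 = strain_pair
    candidates = []
    for _, row in report.iterrows():
        fam = row["family_id"]
        r = row["fold_ratio"]
        if not np.isfinite(row["p_value"]) or row["p_value"] >= p_threshold:
            continue
        if not (r >= fold_threshold or (r > 0 and 1.0 / r >= fold_threshold)):
            continue
        calls = activity.loc[activity["family_id"] == fam, "classification"]
        if (calls == "active-like").sum() == 1:
            candidates.append(fam)
    manifest.record("candidates",
                    {"fold_threshold": fold_threshold,
                     "p_threshold": p_threshold}, ",".join(candidates))
    return ScreenResult(report, profiles, activity, candidates,
                        qc_summaries, manifest)


@dataclass
class CharacterizeResult:
    copies: list[tuple[str, str]]
    annotation: ann.ElementAnnotation
    fragments: phylo.FragmentSet | None
    age_result: phylo.FragmentAgeResult | None
    anova: pd.DataFrame | None
    manifest: RunManifest
    warnings: list[str] = field(default_factory=list)


def run_characterize(
    genome: dict[str, str] | str,
    query: str,
    expression_observations: pd.DataFrame | None = None,
    flank: int = 1000,
    min_copy_identity: float = 0.9,
    max_copies_for_core: int = 3,
    fragment_min_length: int = 100,
    fragment_k: int = 13,
    tir_min_len: int = 20,
    orf_min_codons: int = 50,
    age_model: phylo.AgeModel | None = None,
    seed: int | None = None,
) -> CharacterizeResult:
    """annotate -> collect fragments -> tree -> ages (+ ANOVA if counts)."""
    manifest = RunManifest(seed=seed)
    warnings: list[str] = []
    copies = ann.extract_copies_with_flanks(
        genome, query, flank=flank, min_identity=min_copy_identity,
        min_length=min(len(query) // 2, 500))
    manifest.record("extract", {"flank": flank}, str(len(copies)))
    if len(copies) >= 2:
        core = ann.core_consensus(copies[:max_copies_for_core])
        if not core:
            warnings.append("copies share no high-identity core; "
                            "falling back to the query consensus")
            core = query
    else:
        warnings.append("fewer than 2 genomic copies; using query as core")
        core = query
    annotation = ann.annotate_element(
        core, tir_min_len=tir_min_len, orf_min_codons=orf_min_codons,
        source_copy_ids=[c[0] for c in copies])
    manifest.record("annotate", {"core_length": len(core)}, core)

    exclude = None
    if annotation.tir is not None:
        exclude = (annotation.tir.left[1], annotation.tir.right[0])
    fragments = phylo.collect_fragments(
        genome, core, k=fragment_k, min_length=fragment_min_length,
        exclude_tir=exclude)
    manifest.record("fragments", {"min_length": fragment_min_length},
                    str(len(fragments)))
    age_result = None
    if len(fragments) >= 3:
        age_result = phylo.date_fragments(fragments, age_model)
        manifest.record("ages", {"model": age_model or phylo.AgeModel()},
                        age_result.terminal.to_csv())
    else:
        warnings.append("fewer than 3 fragments; age estimation skipped")

    anova_table = None
    if expression_observations is not None:
        anova_table = expr.sequential_anova(expression_observations)
        manifest.record("anova", {}, anova_table.to_csv())
    return CharacterizeResult(copies, annotation, fragments, age_result,
                              anova_table, manifest, warnings)
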
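"""Central configuration for the virome analysis pipeline.

Every tunable threshold used anywhere in the pipeline lives in
:class:`PipelineConfig`, so that a run is fully described by one config
object plus one integer seed.  The defaults are the study parameters the
pipeline is built around: DeepVirFinder-style score/p cut-offs, the 5%
BUSCO contamination ratio, 95%/75% vOTU clustering, the DIAMOND-style
protein-hit filters, prophage and CRISPR host-assignment thresholds,
1000-permutation PERMANOVA, the |rho| > 0.6 network threshold, and a
1000-tree random forest.

Seeding: a single global seed fans out to per-stage seeds through
:func:`PipelineConfig.stage_seed`, which hashes ``(seed, stage index)``
with :class:`numpy.random.SeedSequence`.  Stages are therefore
individually reproducible and never share a stream.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import numpy as np

#: Pipeline stages in execution order; index = seed-derivation counter.
STAGE_ORDER: tuple[str, ...] = (
    "simulate",
    "triage",
    "derep",
    "annotate",
    "profile",
    "stats",
    "network",
    "classify",
)

_COVERAGE_DENOMINATORS = ("shorter", "query", "subject")
_QUALITY_TIERS = ("complete", "high", "medium", "low", "not-determined")
_RF_EVALUATIONS = ("oob", "cv5", "resub")


@dataclass
class PipelineConfig:
    # --- triage ---------------------------------------------------------
    dvf_p: float = 0.01            # DeepVirFinder p-value cut-off (strict <)
    dvf_score: float = 0.90        # DeepVirFinder score cut-off (strict >)
    busco_ratio: float = 0.05      # remove contig when BUSCO/genes >= this
    # --- vOTU clustering ------------------------------------------------
    identity: float = 95.0         # percent nucleotide identity
    coverage: float = 0.75         # aligned fraction required
    coverage_denominator: str = "shorter"
    word_size: int = 20            # exact seed length for the aligner
    # --- taxonomy vote --------------------------------------------------
    vote_fraction: float = 0.25    # family assigned when share > this
    hit_min_identity: float = 30.0
    hit_min_query_cover: float = 50.0
    hit_min_subject_cover: float = 50.0
    hit_min_bitscore: float = 50.0
    # --- host prediction ------------------------------------------------
    prophage_identity: float = 90.0
    prophage_coverage: float = 0.30  # of the viral sequence
    spacer_bitscore: float = 45.0
    crispr_min_repeats: int = 2
    # --- statistics -----------------------------------------------------
    n_permutations: int = 1000
    alpha: float = 0.05
    rho_threshold: float = 0.6
    fold_line: float = 2.0         # |log2 fold| volcano class boundary
    rarefaction_reps: int = 10
    # --- random forest --------------------------------------------------
    n_trees: int = 1000
    rf_evaluation: str = "oob"
    # --- global ---------------------------------------------------------
    seed: int = 0

    # ------------------------------------------------------------------
    def validate(self) -> list[str]:
        """Return a list of human-readable problems (empty when valid).

        All checks run; errors are aggregated rather than fail-fast.
        """
        errors: list[str] = []

        def _range(name: str, value: float, lo: float, hi: float) -> None:
            if not (lo <= value <= hi):
                errors.append(f"{name}={value!r} outside legal range [{lo}, {hi}]")

        _range("dvf_p", self.dvf_p, 0.0, 1.0)
        _range("dvf_score", self.dvf_score, 0.0, 1.0)
        _range("busco_ratio", self.busco_ratio, 0.0, 1.0)
        _range("identity", self.identity, 0.0, 100.0)
        _range("coverage", self.coverage, 0.0, 1.0)
        if self.coverage_denominator not in _COVERAGE_DENOMINATORS:
            errors.append(
                f"coverage_denominator={self.coverage_denominator!r}; "
                f"legal tokens: {', '.join(_COVERAGE_DENOMINATORS)}"
            )
        if self.word_size < 4:
            errors.append(f"word_size={self.word_size} must be >= 4")
        _range("vote_fraction", self.vote_fraction, 0.0, 1.0)
        _range("hit_min_identity", self.hit_min_identity, 0.0, 100.0)
        _range("hit_min_query_cover", self.hit_min_query_cover, 0.0, 100.0)
        _range("hit_min_subject_cover", self.hit_min_subject_cover, 0.0, 100.0)
        if self.hit_min_bitscore < 0:
            errors.append(f"hit_min_bitscore={self.hit_min_bitscore} must be >= 0")
        _range("prophage_identity", self.prophage_identity, 0.0, 100.0)
        _range("prophage_coverage", self.prophage_coverage, 0.0, 1.0)
        if self.spacer_bitscore < 0:
            errors.append(f"spacer_bitscore={self.spacer_bitscore} must be >= 0")
        if self.crispr_min_repeats < 2:
            errors.append(f"crispr_min_repeats={self.crispr_min_repeats} must be >= 2")
        if self.n_permutations < 1:
            errors.append(f"n_permutations={self.n_permutations} must be >= 1")
        _range("alpha", self.alpha, 0.0, 1.0)
        _range("rho_threshold", self.rho_threshold, 0.0, 1.0)
        if self.fold_line < 0:
            errors.append(f"fold_line={self.fold_line} must be >= 0")
        if self.rarefaction_reps < 1:
            errors.append(f"rarefaction_reps={self.rarefaction_reps} must be >= 1")
        if self.n_trees < 1:
            errors.append(f"n_trees={self.n_trees} must be >= 1")
        if self.rf_evaluation not in _RF_EVALUATIONS:
            errors.append(
                f"rf_evaluation={self.rf_evaluation!r}; "
                f"legal tokens: {', '.join(_RF_EVALUATIONS)}"
            )
        if not (0 <= int(self.seed) < 2**31):
            errors.append(f"seed={self.seed} must be in [0, 2**31)")
        return errors

    def require_valid(self) -> None:
        errors = self.validate()
        if errors:
            raise ValueError("invalid configuration: " + "; ".join(errors))

    # ------------------------------------------------------------------
    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed derived from the global seed."""
        try:
            idx = STAGE_ORDER.index(stage)
        except ValueError:
            raise ValueError(
                f"unknown stage {stage!r}; legal stages: {', '.join(STAGE_ORDER)}"
            ) from None
        state = np.random.SeedSequence([int(self.seed), idx]).generate_state(1)[0]
        return int(state % (2**31))

    # ------------------------------------------------------------------
    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        payload = json.loads(text)
        unknown = set(payload) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**payload)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]
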
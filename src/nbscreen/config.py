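"""Pipeline configuration.

All numeric thresholds used by the filtering and screening code flow from a
single :class:`PipelineConfig` instance so that no filter module carries its
own literals.  The defaults encode the screening protocol this package
implements: population allele frequency strictly below 1%, a heterozygous
VAF window of 40–60% (inclusive), a ±3 intronic splice window with ±1/±2
treated as canonical splice sites, and the 50-nt rule for escape from
nonsense-mediated decay.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import yaml

__all__ = ["PipelineConfig", "load_config"]

FORMAT_VERSION = "1"


@dataclass(frozen=True)
class PipelineConfig:
    """Tunable thresholds for the screening pipeline.

    Parameters
    ----------
    af_cutoff
        Population allele-frequency gate; variants pass only when
        ``population_af < af_cutoff`` (strict inequality).
    vaf_window
        Inclusive [low, high] variant-allele-fraction window used to call a
        heterozygous-looking variant; drives both the VUS-extension trigger
        and carriership detection.
    nmd_rule_nt
        A premature stop escapes nonsense-mediated decay when it falls in
        the last exon or within this many coding nucleotides upstream of the
        final exon–exon junction.
    splice_window
        Intronic offsets up to this distance from an exon boundary count as
        splice-affecting; offsets 1–2 are canonical splice sites.
    vus_trigger_mode
        "exactly_one": the VUS extension fires only for genes with exactly
        one (L)P candidate; "at_least_one" relaxes this.
    strategy
        Default reporting strategy ("strict" or "extended").
    merge_max_gap / merge_vaf_tol
        Parameters for collapsing separately called in-cis events into one
        delins record.
    hom_vaf_min
        VAF at or above which zygosity is inferred homozygous when no
        genotype call is available.
    min_depth
        Below this read depth, VAF-derived zygosity is left unknown.
    count_dup_as_allele
        Whether CNV duplications count as pathogenic alleles (off by
        default; no duplication enters the shipped fixtures).
    emit_inconclusive
        Reserve the "inconclusive" overall call for one-(L)P-plus-conflict
        samples instead of folding them into negative.
    """

    af_cutoff: float = 0.01
    vaf_window: tuple[float, float] = (0.40, 0.60)
    nmd_rule_nt: int = 50
    splice_window: int = 3
    vus_trigger_mode: str = "exactly_one"
    strategy: str = "strict"
    merge_max_gap: int = 10
    merge_vaf_tol: float = 0.1
    hom_vaf_min: float = 0.85
    min_depth: int = 10
    count_dup_as_allele: bool = False
    emit_inconclusive: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.af_cutoff < 1.0):
            raise ValueError(f"af_cutoff must be in (0, 1), got {self.af_cutoff}")
        low, high = self.vaf_window
        if not (0.0 <= low < high <= 1.0):
            raise ValueError(f"invalid vaf_window {self.vaf_window}")
        if self.vus_trigger_mode not in ("exactly_one", "at_least_one"):
            raise ValueError(f"unknown vus_trigger_mode {self.vus_trigger_mode!r}")
        if self.strategy not in ("strict", "extended"):
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if self.nmd_rule_nt < 0 or self.splice_window < 1:
            raise ValueError("nmd_rule_nt must be >= 0 and splice_window >= 1")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["vaf_window"] = list(self.vaf_window)
        d["format_version"] = FORMAT_VERSION
        return d


def load_config(path: str | Path) -> PipelineConfig:
    """Read a :class:`PipelineConfig` from a YAML or JSON file."""
    text = Path(path).read_text()
    data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} does not contain a mapping")
    data.pop("format_version", None)
    if "vaf_window" in data:
        data["vaf_window"] = tuple(data["vaf_window"])
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**data)
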
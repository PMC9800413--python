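"""Pipeline configuration: schema, defaults, and strict validation."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Any, Optional

import yaml

from .pegrna import PegRNA, pegrna_from_dict
from .simulate import SimulationConfig


class ConfigError(ValueError):
    """One or more invalid configuration entries; messages carry key paths."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("; ".join(errors))


@dataclass(frozen=True)
class SearchOptions:
    max_mismatch: int = 4
    max_bulge: int = 2


@dataclass(frozen=True)
class FilterOptions:
    min_mapped_length: int = 30
    flank: int = 150
    nick_tolerance: int = 10
    min_copy: int = 1
    cut_offset: int = 3


@dataclass(frozen=True)
class MapperOptions:
    seed_k: int = 12
    max_mismatch: int = 2


@dataclass(frozen=True)
class AmpliconOptions:
    """Simulated validation stage: amplicon depth and planted frequencies."""

    n_reads: int = 2000
    replicates: int = 3
    major_edited_freq: float = 0.05
    tagmented_freq: float = 0.02
    indel_freq: float = 0.01
    validated_fraction: float = 0.6  # share of planted off-targets truly edited


@dataclass(frozen=True)
class AnalysisOptions:
    match_tolerance: int = 5


@dataclass(frozen=True)
class PipelineConfig:
    pegrna: PegRNA
    seed: int = 0
    genome: Optional[str] = None   # FASTA path; None -> simulated
    reads: Optional[str] = None    # FASTQ path; None -> simulated
    sam: Optional[str] = None      # pre-computed alignments (skips built-in mapper)
    search: SearchOptions = field(default_factory=SearchOptions)
    filters: FilterOptions = field(default_factory=FilterOptions)
    mapper: MapperOptions = field(default_factory=MapperOptions)
    simulate: Optional[SimulationConfig] = None
    amplicon: AmpliconOptions = field(default_factory=AmpliconOptions)
    analysis: AnalysisOptions = field(default_factory=AnalysisOptions)


_SECTION_TYPES = {
    "search": SearchOptions,
    "filters": FilterOptions,
    "mapper": MapperOptions,
    "amplicon": AmpliconOptions,
    "analysis": AnalysisOptions,
}

_TOP_KEYS = {
    "seed", "genome", "reads", "sam", "pegrna", "simulate",
    *_SECTION_TYPES,
}

#: keys whose values must be strictly positive
_POSITIVE = {
    "filters.min_mapped_length", "filters.flank", "filters.nick_tolerance",
    "filters.min_copy", "filters.cut_offset", "mapper.seed_k",
    "search.max_mismatch_plus1",  # max_mismatch itself may be 0
    "amplicon.n_reads", "amplicon.replicates", "analysis.match_tolerance",
}


def _build_section(name: str, cls, raw: dict, errors: list[str]):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    kwargs = {}
    for key, value in raw.items():
        if key not in fields:
            errors.append(f"{name}.{key}: unknown key")
            continue
        kwargs[key] = value
    try:
        obj = cls(**kwargs)
    except (TypeError, ValueError) as exc:
        errors.append(f"{name}: {exc}")
        return cls()
    for f in dataclasses.fields(cls):
        v = getattr(obj, f.name)
        path = f"{name}.{f.name}"
        if isinstance(v, bool) or not isinstance(v, (int, float)):
            continue
        if path in _POSITIVE and v <= 0:
            errors.append(f"{path}: must be positive, got {v}")
        elif v < 0:
            errors.append(f"{path}: must be non-negative, got {v}")
    return obj


def validate_config(raw: Optional[dict], seed_override: Optional[int] = None) -> PipelineConfig:
    """Normalize a parsed config mapping: inject defaults, reject unknown keys.

    Raises :class:`ConfigError` listing every problem with its key path.  An
    empty file yields the all-defaults configuration (with a toy pegRNA
    requirement: the ``pegrna`` block may be omitted only when simulating,
    in which case a built-in example pegRNA is used).
    """
    raw = dict(raw or {})
    errors: list[str] = []
    for key in raw:
        if key not in _TOP_KEYS:
            errors.append(f"{key}: unknown key")

    sections = {}
    for name, cls in _SECTION_TYPES.items():
        block = raw.get(name) or {}
        if not isinstance(block, dict):
            errors.append(f"{name}: expected a mapping")
            block = {}
        sections[name] = _build_section(name, cls, block, errors)

    sim = None
    if "simulate" in raw and raw["simulate"] is not None:
        block = raw["simulate"]
        if not isinstance(block, dict):
            errors.append("simulate: expected a mapping")
        else:
            sim_fields = {f.name for f in dataclasses.fields(SimulationConfig)}
            kwargs = {}
            for key, value in block.items():
                if key not in sim_fields:
                    errors.append(f"simulate.{key}: unknown key")
                else:
                    kwargs[key] = value
            try:
                sim = SimulationConfig(**kwargs)
            except (TypeError, ValueError) as exc:
                errors.append(f"simulate: {exc}")

    pegrna = None
    if "pegrna" in raw and raw["pegrna"] is not None:
        try:
            pegrna = pegrna_from_dict(raw["pegrna"])
        except Exception as exc:
            errors.append(f"pegrna: {exc}")
    if pegrna is None and not errors:
        pegrna = example_pegrna()

    seed = raw.get("seed", 0)
    if seed_override is not None:
        seed = seed_override
    if not isinstance(seed, int):
        errors.append(f"seed: expected an integer, got {seed!r}")
        seed = 0

    if errors:
        raise ConfigError(errors)
    if sim is not None and seed_override is not None:
        sim = dataclasses.replace(sim, seed=seed)
    if sim is not None and "seed" not in (raw.get("simulate") or {}):
        sim = dataclasses.replace(sim, seed=seed)
    return PipelineConfig(
        pegrna=pegrna,
        seed=seed,
        genome=raw.get("genome"),
        reads=raw.get("reads"),
        sam=raw.get("sam"),
        simulate=sim,
        **sections,
    )


def load_config(path, seed_override: Optional[int] = None) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if raw is not None and not isinstance(raw, dict):
        raise ConfigError([f"{path}: expected a mapping at the top level"])
    return validate_config(raw, seed_override)


def example_pegrna() -> PegRNA:
    """Built-in toy pegRNA: a +2 G-to-T substitution with the default tag.

    The spacer/PBS/RT sequences are this package's own example derived from a
    fixed genomic context (see :func:`petag.simulate.example_target`), not
    any study's sequences.
    """
    from .simulate import example_target

    return example_target()[0]


def config_hash(config: PipelineConfig) -> str:
    """Stable hash of the normalized configuration (drives --resume)."""

    def encode(obj: Any):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {f.name: encode(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
        if isinstance(obj, (list, tuple)):
            return [encode(x) for x in obj]
        return obj

    blob = json.dumps(encode(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()
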
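"""Run configuration: defaults, the key=value config file, and parsing.

Config keys follow the historical parameter spellings (MIN_ALLEL_CNT,
SPECIAL_DIF, MIN_FLANK_LEN, MAX_DIFF_TM, ...) so a settings file can be
eyeballed against published runs.  Unknown keys warn; a bad value for a
known key is fatal and names the key.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

from .mining import DEFAULT_MIN_REPEATS, SSR_TYPES
from .preprocess import MergeParams, TrimParams
from .primers import PrimerParams

_ANCHORS = ("start", "end", "either", "anywhere")


class ConfigError(ValueError):
    """Unparseable value for a known configuration key."""


@dataclass
class PipelineConfig:
    """Every tunable of the pipeline with its default.

    Defaults mirror the published run where one was stated (minimum
    observed alleles 5, minimum flank 50 bp, pair Tm difference 0.5 C,
    clustering at 0.90 identity with word size 10) and the delegated
    tools' conventional defaults elsewhere.
    """

    adapter_seqs: list[str] = field(default_factory=lambda: ["AGATCGGAAGAGC"])
    restriction_pattern: str = ""
    restriction_anchor: str = "either"
    excluded_ssr_types: set[str] = field(default_factory=set)
    min_allele_cnt: int = 5
    special_search: bool = False
    special_min_potential: int = 8
    min_flank_len: int = 50
    min_motif_repetition: int = 2
    min_repeats: dict[int, int] = field(
        default_factory=lambda: dict(DEFAULT_MIN_REPEATS)
    )
    compound_max_gap: int = 100
    cluster_identity: float = 0.90
    cluster_word_size: int = 10
    min_cluster_members: int = 2
    require_motif_consistency: bool = False
    max_diff_tm: float = 0.5
    product_size_range: tuple[int, int] = (100, 300)
    primer: PrimerParams = field(default_factory=PrimerParams)
    avoid_primer_in_ssr: bool = False
    prefix: str = "Locus"
    rng_seed: int = 1
    trim: TrimParams = field(default_factory=TrimParams)
    merge: MergeParams = field(default_factory=MergeParams)

    def __post_init__(self) -> None:
        if self.product_size_range[0] > self.product_size_range[1]:
            raise ConfigError("PRODUCT_SIZE_RANGE: min > max")
        if self.min_allele_cnt < 1:
            raise ConfigError("MIN_ALLEL_CNT must be >= 1")
        if self.restriction_anchor not in _ANCHORS:
            raise ConfigError(
                f"RESTRICTION_ANCHOR must be one of {', '.join(_ANCHORS)}"
            )
        bad = self.excluded_ssr_types - SSR_TYPES
        if bad:
            raise ConfigError(f"EXCLUDED_SSR_TYPES: unknown types {sorted(bad)}")


def _parse_bool(text: str) -> bool:
    t = text.strip().lower()
    if t in ("on", "true", "yes", "1"):
        return True
    if t in ("off", "false", "no", "0"):
        return False
    raise ValueError(f"not a boolean: {text!r}")


def _parse_range(text: str) -> tuple[int, int]:
    lo, hi = text.replace(",", "-").split("-")
    return (int(lo), int(hi))


def _parse_min_repeats(text: str) -> dict[int, int]:
    """e.g. "1-10,2-6,3-5,4-5,5-5,6-5" (unit length - minimum repeats)."""
    out = dict(DEFAULT_MIN_REPEATS)
    for part in text.replace(";", ",").split(","):
        if not part.strip():
            continue
        u, k = part.strip().split("-")
        out[int(u)] = int(k)
    return out


# key -> (config attribute path, parser)
CONFIG_KEYS: dict[str, tuple[str, object]] = {
    "ADAPTERS": ("adapter_seqs", lambda s: [a.strip().upper() for a in s.split(",") if a.strip()]),
    "RESTRICTION_PATTERN": ("restriction_pattern", lambda s: s.strip().upper()),
    "RESTRICTION_ANCHOR": ("restriction_anchor", lambda s: s.strip().lower()),
    "EXCLUDED_SSR_TYPES": ("excluded_ssr_types", lambda s: {t.strip() for t in s.split(",") if t.strip()}),
    "MIN_ALLEL_CNT": ("min_allele_cnt", int),
    "SPECIAL_SEARCH": ("special_search", _parse_bool),
    "SPECIAL_DIF": ("special_min_potential", int),
    "MIN_FLANK_LEN": ("min_flank_len", int),
    "MIN_MOTIF_REPETITION": ("min_motif_repetition", int),
    "MIN_REPEATS": ("min_repeats", _parse_min_repeats),
    "COMPOUND_MAX_GAP": ("compound_max_gap", int),
    "CLUSTER_IDENTITY": ("cluster_identity", float),
    "CLUSTER_WORD_SIZE": ("cluster_word_size", int),
    "MIN_CLUSTER_MEMBERS": ("min_cluster_members", int),
    "MOTIF_CONSISTENCY": ("require_motif_consistency", _parse_bool),
    "MAX_DIFF_TM": ("max_diff_tm", float),
    "PRODUCT_SIZE_RANGE": ("product_size_range", _parse_range),
    "PRIMER_SIZE_MIN": ("primer.size_min", int),
    "PRIMER_SIZE_OPT": ("primer.size_opt", int),
    "PRIMER_SIZE_MAX": ("primer.size_max", int),
    "PRIMER_TM_MIN": ("primer.tm_min", float),
    "PRIMER_TM_OPT": ("primer.tm_opt", float),
    "PRIMER_TM_MAX": ("primer.tm_max", float),
    "PRIMER_GC_MIN": ("primer.gc_min", lambda s: float(s) / 100.0),
    "PRIMER_GC_MAX": ("primer.gc_max", lambda s: float(s) / 100.0),
    "PRIMER_MAX_POLY": ("primer.max_homopolymer", int),
    "PRIMER_MAX_SELF_COMP": ("primer.max_self_comp", int),
    "PRIMER_NUM_RETURN": ("primer.num_return", int),
    "AVOID_PRIMER_IN_SSR": ("avoid_primer_in_ssr", _parse_bool),
    "PREFIX": ("prefix", lambda s: s.strip()),
    "RNG_SEED": ("rng_seed", int),
    "TRIM_WINDOW": ("trim.window", int),
    "TRIM_MIN_QUAL": ("trim.min_mean_q", float),
    "TRIM_MIN_LEN": ("trim.min_len", int),
    "ADAPTER_MAX_ERROR_RATE": ("trim.adapter_max_error_rate", float),
    "MERGE_MIN_OVERLAP": ("merge.min_overlap", int),
    "MERGE_MAX_MISMATCH_DENSITY": ("merge.max_mismatch_density", float),
}


def apply_setting(cfg: PipelineConfig, key: str, raw: str) -> None:
    """Apply one KEY=value setting in place; fatal on a bad value."""
    key = key.strip().upper()
    if key not in CONFIG_KEYS:
        warnings.warn(f"unknown configuration key {key!r} ignored", stacklevel=2)
        return
    attr, parser = CONFIG_KEYS[key]
    try:
        value = parser(raw)
    except Exception as exc:
        raise ConfigError(f"bad value for {key}: {raw!r} ({exc})") from None
    obj = cfg
    *parents, leaf = attr.split(".")
    for p in parents:
        obj = getattr(obj, p)
    setattr(obj, leaf, value)


def read_config(path) -> PipelineConfig:
    """Parse a key=value settings file ('#' comments and blanks ignored).

    Missing keys keep their documented defaults; unknown keys warn.
    """
    cfg = PipelineConfig()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ConfigError(f"{path}: line {lineno}: expected KEY=value")
            key, raw = line.split("=", 1)
            apply_setting(cfg, key, raw.strip())
    # re-run cross-field validation
    cfg.__post_init__()
    return cfg
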
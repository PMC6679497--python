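"""Run configuration: every knob of the screen in one validated record.

The defaults implement the intended reading of each score (distance decay,
most-informative common ancestor) rather than the degenerate literal
variants, which remain available behind flags for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path

import yaml

from .errors import ConfigError

_CHOICES = {
    "exponent_sign": ("decay", "literal"),
    "scoring_graph": ("disease", "background", "disease_plus_targets"),
    "mica_rule": ("mica", "literal_max"),
    "aggregation": ("max", "bma", "avg"),
    "corpus_scope": ("all_annotations", "target_union"),
    "missing_3d": ("zero", "skip_axis"),
    "total_rule": ("diagonal", "sum", "euclidean"),
}


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration for a synergy screen.

    Parameters
    ----------
    exponent_sign
        ``decay`` uses exp(-D/n^2) so nearby targets score higher;
        ``literal`` uses exp(+D/n^2).
    scoring_graph
        Which network carries centralities and distances: the induced
        disease subnetwork, the full background network, or the disease
        genes plus both drugs' targets.
    damping
        PageRank damping factor in (0, 1).
    mica_rule
        ``mica`` picks the common ancestor with minimum annotation
        probability (maximum information content); ``literal_max`` picks
        maximum probability.
    aggregation
        Cross-term aggregation for multiply-annotated genes:
        ``max``, ``bma`` (best-match average) or ``avg``.
    corpus_scope
        Whether term frequencies come from the whole annotation corpus or
        only from annotations of the drugs' target union.
    q
        LINGO substring length in characters.
    sigma
        Gaussian width of the pharmacophore overlap kernel, in angstroms.
    missing_3d
        Policy when a drug lacks 3D site data: score 0 or drop the axis.
    total_rule
        How normalized axes combine into the ranking total.
    conf_level
        Two-sided confidence level for trial statistics.
    seed
        Seed forwarded to fixture generators; None means caller-managed.
    """

    exponent_sign: str = "decay"
    scoring_graph: str = "disease"
    damping: float = 0.85
    mica_rule: str = "mica"
    aggregation: str = "max"
    corpus_scope: str = "all_annotations"
    q: int = 4
    sigma: float = 1.0
    missing_3d: str = "zero"
    total_rule: str = "diagonal"
    conf_level: float = 0.95
    seed: int | None = None

    def __post_init__(self):
        for key, allowed in _CHOICES.items():
            value = getattr(self, key)
            if value not in allowed:
                raise ConfigError(
                    f"config key {key!r}: {value!r} not in {allowed}",
                    code="config.invalid",
                )
        if not 0 < self.damping < 1:
            raise ConfigError("config key 'damping': must be in (0, 1)")
        if not isinstance(self.q, int) or self.q < 1:
            raise ConfigError("config key 'q': must be an integer >= 1")
        if self.sigma <= 0:
            raise ConfigError("config key 'sigma': must be > 0")
        if not 0 < self.conf_level < 1:
            raise ConfigError("config key 'conf_level': must be in (0, 1)")
        if self.seed is not None and not isinstance(self.seed, int):
            raise ConfigError("config key 'seed': must be an integer or null")


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load a YAML config file, or return all defaults when ``path`` is None.

    Unknown keys are rejected by name so typos never pass silently.
    """
    if path is None:
        return RunConfig()
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text()) or {}
    except OSError as exc:
        raise ConfigError(f"cannot read config file {path}: {exc}",
                          code="io.unreadable") from exc
    except yaml.YAMLError as exc:
        raise ConfigError(f"malformed config file {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"config file {path} must hold a mapping")
    known = {f.name for f in fields(RunConfig)}
    unknown = sorted(set(raw) - known)
    if unknown:
        raise ConfigError(
            f"unknown config key(s): {', '.join(map(repr, unknown))}")
    return RunConfig(**raw)
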
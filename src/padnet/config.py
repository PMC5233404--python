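"""Run configuration: every tunable parameter of the pipeline in one place."""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Mapping

_BOOL_TRUE = {"1", "true", "yes", "on"}
_BOOL_FALSE = {"0", "false", "no", "off"}


@dataclass
class RunConfig:
    """Pipeline parameters with their standard defaults.

    ``p_pathway`` (0.01) selects per-dataset significant pathways;
    ``p_candidate`` (0.001) selects repositioning candidates from the
    Gaussian tail; ``weight_min`` (0.4, strict) and ``neighbor_cap`` (40)
    filter the validation network; ``damping`` (0.85) is the PageRank
    damping factor.  ``seed`` is mandatory so every permutation and
    simulation stream is reproducible.
    """

    seed: int
    n_perm: int = 1000
    p_pathway: float = 0.01
    p_candidate: float = 0.001
    alpha: float = 0.8
    tol: float = 1e-6
    max_iter: int = 1000
    weight_exponent: float = 1.0
    weight_transform: str = "abs"
    edge_threshold: float = 0.0
    min_overlap: int = 5
    weight_min: float = 0.4
    neighbor_cap: int = 40
    damping: float = 0.85
    case_insensitive_ids: bool = True

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is required")
        self.seed = int(self.seed)
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        for name, lo, hi in (
            ("p_pathway", 0.0, 1.0),
            ("p_candidate", 0.0, 1.0),
            ("alpha", 0.0, 1.0),
            ("damping", 0.0, 1.0),
        ):
            v = getattr(self, name)
            if not lo < v < hi:
                raise ValueError(f"{name} must lie strictly between {lo} and {hi}, got {v}")
        if self.tol <= 0 or self.max_iter < 1:
            raise ValueError("tol must be > 0 and max_iter >= 1")
        if self.weight_exponent < 0 or self.edge_threshold < 0 or self.weight_min < 0:
            raise ValueError("weight_exponent, edge_threshold and weight_min must be >= 0")
        if self.weight_transform not in ("abs", "positive-only"):
            raise ValueError("weight_transform must be 'abs' or 'positive-only'")
        if self.neighbor_cap < 1 or self.min_overlap < 1:
            raise ValueError("neighbor_cap and min_overlap must be >= 1")

    def to_mapping(self) -> dict[str, str]:
        return {k: str(v) for k, v in asdict(self).items()}

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, str]) -> "RunConfig":
        """Build from a flat string mapping (unknown keys ignored)."""
        kwargs: dict = {}
        fields = cls.__dataclass_fields__
        for key, raw in mapping.items():
            if key not in fields:
                continue
            typ = fields[key].type
            if typ == "int":
                kwargs[key] = int(raw)
            elif typ == "float":
                kwargs[key] = float(raw)
            elif typ == "bool":
                low = str(raw).strip().lower()
                if low in _BOOL_TRUE:
                    kwargs[key] = True
                elif low in _BOOL_FALSE:
                    kwargs[key] = False
                else:
                    raise ValueError(f"cannot parse boolean config value {key}={raw!r}")
            else:
                kwargs[key] = str(raw)
        if "seed" not in kwargs:
            raise ValueError("config must provide a seed")
        return cls(**kwargs)
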
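"""Pipeline configuration: nested dataclasses with lossless YAML round-trip."""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .binarize import ThresholdPair  # noqa: F401  (re-export convenience)
from .coherence import DiffusionParams, RidgeBankConfig, scale_normalization_case
from .enhance import HomomorphicParams, WienerParams
from .exceptions import ParameterError
from .morphology import StructuringElement

__all__ = ["BinarizeConfig", "PipelineConfig"]


@dataclass(frozen=True)
class BinarizeConfig:
    k_std: float = 0.7
    edge_fraction: float = 0.1
    min_area: int = 70
    connectivity: int = 8
    tail: str = "bright"  # which histogram tail holds the vessels


@dataclass(frozen=True)
class PipelineConfig:
    """Every knob of the segmentation pipeline, with ablation switches.

    The ablation flags mirror the method's "without enhancement"
    comparisons; ``case`` selects the scale-normalization exponents
    (default case 2, alpha=1, beta=0.5).  ``polarity`` says which ridge
    polarity the detector hunts: "dark-ridge" negates inputs whose vessels
    are bright (the morphology stage maps vessels to high values).
    """

    morphology: StructuringElement = field(default_factory=StructuringElement)
    homomorphic: HomomorphicParams = field(default_factory=HomomorphicParams)
    wiener: WienerParams = field(default_factory=WienerParams)
    ridge: RidgeBankConfig = field(default_factory=RidgeBankConfig)
    diffusion: DiffusionParams = field(default_factory=DiffusionParams)
    binarize: BinarizeConfig = field(default_factory=BinarizeConfig)
    channel: str = "auto"  # auto | red | green | blue
    case: int | None = 2
    polarity: str = "dark-ridge"
    border_iterations: int = 30
    enable_morphology: bool = True
    enable_homomorphic: bool = True
    enable_wiener: bool = True
    enable_diffusion: bool = True

    def __post_init__(self):
        if self.channel not in ("auto", "red", "green", "blue"):
            raise ParameterError(f"unknown channel selection {self.channel!r}")
        if self.polarity not in ("dark-ridge", "bright-ridge"):
            raise ParameterError(f"unknown polarity {self.polarity!r}")
        if self.case is not None:
            scale_normalization_case(self.case)  # validates

    def ridge_with_case(self) -> RidgeBankConfig:
        """Ridge config with (alpha, beta) overridden by the selected case."""
        if self.case is None:
            return self.ridge
        alpha, beta = scale_normalization_case(self.case)
        return RidgeBankConfig(
            sigma_v_set=self.ridge.sigma_v_set,
            elongation_factors=self.ridge.elongation_factors,
            orientation_step=self.ridge.orientation_step,
            alpha=alpha, beta=beta,
            kernel_truncate=self.ridge.kernel_truncate)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        builders = {
            "morphology": StructuringElement,
            "homomorphic": HomomorphicParams,
            "wiener": WienerParams,
            "ridge": RidgeBankConfig,
            "diffusion": DiffusionParams,
            "binarize": BinarizeConfig,
        }
        kwargs = {}
        for key, builder in builders.items():
            if key in d:
                sub = dict(d.pop(key))
                for k, v in sub.items():  # YAML lists -> tuples for frozen fields
                    if isinstance(v, list):
                        sub[k] = tuple(v)
                kwargs[key] = builder(**sub)
        kwargs.update(d)
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
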
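"""Pipeline configuration.

Defaults follow the published operating point of the method: Gaussian
flattening FWHM f_NU = 20 mm, difference-of-Gaussian FWHMs f_1 = 10 mm and
f_2 = 5 mm, slice-pruning threshold z_poly = 1.5, eye-pair weight lambda = 4,
eye-plane tilt theta = 30 deg, eye clustering radius 0.75 x OD and success
radius 1.2 x OD. MSER stability parameters are engineering choices (the
anatomical filter banks do the real selection) and are exposed here.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml


@dataclass
class MserParams:
    """Stability parameters for extremal-region detection.

    delta is expressed on the quantized 256-level scale; max_area is a
    fraction of the slice area. Bounds are deliberately loose: the
    age-specific anatomical filters downstream do the real selection.
    """

    delta: int = 5
    min_area: int = 9
    max_area_frac: float = 0.4
    max_variation: float = 0.5
    min_diversity: float = 0.2
    n_levels: int = 256


@dataclass
class PipelineConfig:
    # per-slice intensity preparation (mm FWHM)
    f_nu: float = 20.0
    f_1: float = 10.0
    f_2: float = 5.0
    # mean-shift clustering: kernel FWHM = f_clust_factor x OFD
    f_clust_factor: float = 0.5
    meanshift_grid_factor: float = 0.5   # grid spacing = factor x OFD
    meanshift_tol_mm: float = 1.0
    meanshift_max_iter: int = 100
    # brain-mask regularization
    z_poly: float = 1.5
    # eye stage
    lam: float = 4.0                     # pair-error symmetry weight
    rho_clust_factor: float = 0.75       # eye cluster radius = factor x OD
    d_io_factor: float = 2.0             # expected eye separation = factor x OD
    # anatomical frame
    theta_deg: float = 30.0              # eye-plane tilt about LR
    tilt_sign: int = 1                   # flip for the opposite convention
    # evaluation
    rho_success_factor: float = 1.2
    # detectors
    mser: MserParams = field(default_factory=MserParams)
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        mser = d.pop("mser", None)
        cfg = cls(**{k: v for k, v in d.items()})
        if mser is not None:
            cfg.mser = MserParams(**mser)
        return cfg

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        """Load overrides from a YAML (or JSON, a YAML subset) file."""
        with open(path) as f:
            data = yaml.safe_load(f) or {}
        base = cls().to_dict()
        mser = base.pop("mser")
        mser.update(data.pop("mser", {}))
        base.update(data)
        base["mser"] = mser
        return cls.from_dict(base)
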
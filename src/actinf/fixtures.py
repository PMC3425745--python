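"""Synthetic stimuli, toy oracle models and scenario presets.

Everything an experiment needs is generated programmatically: face-like
grayscale templates (parametric geometry, no image assets), their
inverted/rotated variants, closed-form linear-Gaussian toy models used
as analytic oracles, and named scenario presets that pin down every free
parameter of the two flagship simulations.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import yaml
from scipy import ndimage

from .exceptions import ConfigurationError
from .hdm import HierarchicalModel, ModelLevel, _as_spd
from .visual_world import TemplateImage, HypothesisSet

__all__ = [
    "FaceSpec",
    "render_face",
    "transform_template",
    "default_hypotheses",
    "ToyLinearGaussian",
    "toy_linear_gaussian_model",
    "load_scenario",
    "available_scenarios",
]


@dataclass
class FaceSpec:
    """Parameters of the parametric face-like template.

    All feature parameters are in units relative to the image half-size;
    the rendered image is ``size x size`` with values in [0, 1].
    """

    size: int = 33
    eye_separation: float = 0.55
    eye_height: float = 0.35
    eye_radius: float = 0.13
    mouth_height: float = -0.42
    mouth_width: float = 0.5
    mouth_curvature: float = 0.25
    outline_width: float = 0.08
    contrast: float = 1.0
    seed: int = 0


def render_face(spec: FaceSpec) -> TemplateImage:
    """Render a deterministic grayscale face-like pattern.

    An elliptical outline, two eyes and a curved mouth, drawn with
    smooth (Gaussian-profile) strokes so the image is differentiable
    under bilinear sampling.  Features are left-right symmetric by
    default, so the image equals its horizontal mirror.
    """
    if spec.size < 16:
        raise ConfigurationError(f"face size must be >= 16 pixels, got {spec.size}")
    s = spec.size
    # coordinate grid in [-1, 1], x rightward, y upward
    ys, xs = np.mgrid[0:s, 0:s]
    x = (xs - (s - 1) / 2) / ((s - 1) / 2)
    y = ((s - 1) / 2 - ys) / ((s - 1) / 2)

    img = np.zeros((s, s))
    # outline: ring at the ellipse r=0.9 with soft width
    r = np.sqrt((x / 0.78) ** 2 + (y / 0.95) ** 2)
    img += np.exp(-((r - 0.9) ** 2) / (2 * spec.outline_width**2))
    # eyes: two filled soft discs
    for sx in (-1.0, 1.0):
        d2 = (x - sx * spec.eye_separation / 2 * 2) ** 2 + (y - spec.eye_height) ** 2
        img += np.exp(-d2 / (2 * spec.eye_radius**2))
    # mouth: soft arc y = h + curvature*(x/w)^2 within |x| <= w
    mouth_y = spec.mouth_height + spec.mouth_curvature * (x / spec.mouth_width) ** 2
    stroke = np.exp(-((y - mouth_y) ** 2) / (2 * 0.06**2))
    stroke *= np.exp(-np.clip(np.abs(x) - spec.mouth_width, 0, None) ** 2 / (2 * 0.05**2))
    img += stroke

    img = np.clip(img, 0.0, 1.0) * float(np.clip(spec.contrast, 0.0, 1.0))
    return TemplateImage(pixels=img, label="upright")


def transform_template(img: TemplateImage, op: str, angle: float = 90.0) -> TemplateImage:
    """Invert (vertical flip) or rotate a template about its centre.

    Rotation is clockwise in degrees; exact multiples of 90 use an exact
    pixel permutation, other angles use bilinear interpolation with
    background fill 0.
    """
    if op == "invert":
        return TemplateImage(pixels=np.flipud(img.pixels).copy(),
                             label="inverted", extent=img.extent)
    if op == "rotate":
        a = float(angle) % 360.0
        if np.isclose(a % 90.0, 0.0):
            k = int(round(a / 90.0)) % 4
            # np.rot90 rotates counter-clockwise; clockwise is k negated
            px = np.rot90(img.pixels, -k).copy()
        else:
            px = ndimage.rotate(img.pixels, -a, reshape=False, order=1,
                                mode="constant", cval=0.0)
            px = np.clip(px, 0.0, 1.0)
        return TemplateImage(pixels=px, label="rotated", extent=img.extent)
    raise ConfigurationError(f"unknown template transform {op!r}; use 'invert' or 'rotate'")


def default_hypotheses(spec: FaceSpec | None = None, angle: float = 90.0,
                       true_index: int = 0) -> HypothesisSet:
    """The canonical three-hypothesis set: upright, inverted, rotated face."""
    spec = spec or FaceSpec()
    upright = render_face(spec)
    return HypothesisSet(
        templates=[
            upright,
            transform_template(upright, "invert"),
            transform_template(upright, "rotate", angle),
        ],
        true_index=true_index,
    )


# ---------------------------------------------------------------------------
# analytic oracle models
# ---------------------------------------------------------------------------

@dataclass
class ToyLinearGaussian:
    """A one-level static linear-Gaussian model with its exact posterior."""

    model: HierarchicalModel
    A: np.ndarray
    s_tilde: np.ndarray           # (1, ny) generalised data (static: order 1)
    prior_mean: np.ndarray
    posterior_mean: np.ndarray
    posterior_cov: np.ndarray


def toy_linear_gaussian_model(
    nv: int = 2,
    ny: int = 3,
    sensory_precision: float | np.ndarray = 2.0,
    prior_precision: float | np.ndarray = 1.0,
    seed: int = 0,
) -> ToyLinearGaussian:
    """Static model s = A v + noise with conjugate-Gaussian posterior.

    The exact posterior has precision ``A' Pi_z A + Pi_v`` and mean
    ``cov (A' Pi_z s + Pi_v eta)``; it is the closed-form oracle for
    perception tests.
    """
    rng = np.random.default_rng(seed)
    A = rng.normal(size=(ny, nv))
    eta = rng.normal(size=nv)
    v_true = rng.normal(size=nv)
    s = A @ v_true + 0.1 * rng.normal(size=ny)
    Pi_z = _as_spd(sensory_precision, ny, "sensory_precision")
    Pi_v = _as_spd(prior_precision, nv, "prior_precision")

    level = ModelLevel(
        ny=ny, nx=0, nv=nv,
        g=lambda x, v: A @ v,
        jac_g=lambda x, v: (np.zeros((ny, 0)), A),
        output_precision=Pi_z,
    )
    model = HierarchicalModel([level], order=1, prior_mean=eta,
                              prior_precision=Pi_v)
    post_prec = A.T @ Pi_z @ A + Pi_v
    post_cov = np.linalg.inv(post_prec)
    post_mean = post_cov @ (A.T @ Pi_z @ s + Pi_v @ eta)
    return ToyLinearGaussian(
        model=model, A=A, s_tilde=s.reshape(1, ny), prior_mean=eta,
        posterior_mean=post_mean, posterior_cov=post_cov,
    )


# ---------------------------------------------------------------------------
# scenario presets
# ---------------------------------------------------------------------------

def available_scenarios() -> list[str]:
    root = importlib.resources.files("actinf") / "presets"
    return sorted(p.name[:-5] for p in root.iterdir() if p.name.endswith(".yaml"))


def load_scenario(name: str) -> dict:
    """Load a named preset (or a YAML path) into a flat-ish config dict."""
    root = importlib.resources.files("actinf") / "presets"
    res = root / f"{name}.yaml"
    try:
        text = res.read_text()
    except (FileNotFoundError, OSError):
        try:
            with open(name) as fh:
                text = fh.read()
        except OSError as exc:
            raise ConfigurationError(
                f"unknown scenario {name!r}; available: {available_scenarios()}"
            ) from exc
    cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise ConfigurationError(f"scenario {name!r} did not parse to a mapping")
    return cfg
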
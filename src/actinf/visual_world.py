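"""Generative model and world for the saccadic visual-search experiment.

The agent entertains K competing image hypotheses (templates).  Its
hidden states are two oculomotor coordinates (gaze displacement) and K
hypothesis log-propensities; a softmax of the latter weights the
templates into a single visual prediction, sampled through a foveated
sensor whose precision falls off with retinal eccentricity.  The world
contains one true template; action displaces the physical gaze, which
determines what the fovea actually samples.

Gaze coordinates are continuous, origin at the image centre, x rightward
(columns), y upward (rows reversed), unit = half-extent of the image.
Sampling outside the image returns the background value 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .exceptions import ConfigurationError, ModelSpecificationError
from .hdm import HierarchicalModel, ModelLevel

__all__ = [
    "TemplateImage",
    "HypothesisSet",
    "FovealSampler",
    "SearchParams",
    "softmax",
    "foveal_sample",
    "sensory_mapping_g",
    "hidden_dynamics_f",
    "make_search_model",
    "VisualWorld",
]


def softmax(z: np.ndarray) -> np.ndarray:
    z = np.asarray(z, dtype=float)
    e = np.exp(z - np.max(z))
    return e / e.sum()


@dataclass
class TemplateImage:
    """Grayscale template; ``extent`` is the half-width in gaze units."""

    pixels: np.ndarray
    label: str = ""
    extent: float = 1.0

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2:
            raise ConfigurationError("template pixels must be a 2-D array")
        if px.min() < -1e-12 or px.max() > 1 + 1e-12:
            raise ConfigurationError("template values must lie in [0, 1]")
        self.pixels = np.clip(px, 0.0, 1.0)

    def save_pgm(self, path) -> None:
        """Write as binary PGM (P5), 8-bit."""
        arr = np.round(self.pixels * 255).astype(np.uint8)
        h, w = arr.shape
        with open(path, "wb") as fh:
            fh.write(f"P5\n{w} {h}\n255\n".encode())
            fh.write(arr.tobytes())

    def save_png(self, path) -> None:
        from PIL import Image

        arr = np.round(self.pixels * 255).astype(np.uint8)
        Image.fromarray(arr, mode="L").save(path)

    @classmethod
    def load(cls, path, label: str = "", extent: float = 1.0) -> "TemplateImage":
        from PIL import Image

        arr = np.asarray(Image.open(path).convert("L"), dtype=float) / 255.0
        return cls(pixels=arr, label=label, extent=extent)


@dataclass
class HypothesisSet:
    """Ordered competing templates plus the index generating the data."""

    templates: list
    true_index: int = 0

    def __post_init__(self) -> None:
        if len(self.templates) < 1:
            raise ConfigurationError("hypothesis set needs at least one template")
        if not (0 <= self.true_index < len(self.templates)):
            raise ConfigurationError(f"true_index {self.true_index} out of range")
        shapes = {t.pixels.shape for t in self.templates}
        extents = {t.extent for t in self.templates}
        if len(shapes) > 1 or len(extents) > 1:
            raise ConfigurationError("all templates must share grid shape and extent")

    @property
    def K(self) -> int:
        return len(self.templates)


class FovealSampler:
    """Retinal sample offsets with an eccentricity-dependent precision.

    Offsets form a regular ``grid_side x grid_side`` lattice clipped to a
    disc of radius ``2 sigma_fov``; the per-offset sensory precision is
    ``max_precision * exp(-ecc^2 / (2 sigma_fov^2))``, maximal at the
    fovea (zero eccentricity) and strictly decreasing outward.
    """

    def __init__(self, sigma_fov: float = 0.25, grid_side: int = 9,
                 max_precision: float = 8.0):
        if sigma_fov <= 0 or max_precision <= 0 or grid_side < 1:
            raise ConfigurationError("sigma_fov, max_precision and grid_side must be positive")
        self.sigma_fov = float(sigma_fov)
        self.max_precision = float(max_precision)
        lin = np.linspace(-2 * sigma_fov, 2 * sigma_fov, grid_side)
        xx, yy = np.meshgrid(lin, lin)
        pts = np.column_stack([xx.ravel(), yy.ravel()])
        ecc = np.linalg.norm(pts, axis=1)
        keep = ecc <= 2 * sigma_fov + 1e-12
        self.offsets = pts[keep]
        self.eccentricity = ecc[keep]
        self.precision_profile = max_precision * np.exp(
            -self.eccentricity**2 / (2 * sigma_fov**2)
        )

    @property
    def R(self) -> int:
        return len(self.offsets)


def _to_pixel_coords(positions: np.ndarray, shape, extent: float) -> np.ndarray:
    """Gaze-unit (x, y) points -> fractional (row, col) pixel coordinates."""
    h, w = shape
    x = positions[..., 0]
    y = positions[..., 1]
    col = (x + extent) / (2 * extent) * (w - 1)
    row = (extent - y) / (2 * extent) * (h - 1)
    return np.stack([row, col])


def sample_image(image: TemplateImage, positions: np.ndarray) -> np.ndarray:
    """Bilinear samples of ``image`` at gaze-unit positions (..., 2).

    Positions outside the extent return the background value 0.
    """
    positions = np.asarray(positions, dtype=float)
    coords = _to_pixel_coords(positions, image.pixels.shape, image.extent)
    flat = coords.reshape(2, -1)
    vals = ndimage.map_coordinates(image.pixels, flat, order=1,
                                   mode="constant", cval=0.0)
    return vals.reshape(positions.shape[:-1])


def foveal_sample(image: TemplateImage, gaze: np.ndarray,
                  sampler: FovealSampler) -> np.ndarray:
    """Foveated sample vector: the image at gaze + each retinal offset."""
    gaze = np.asarray(gaze, dtype=float).reshape(2)
    if not np.all(np.isfinite(gaze)):
        raise ConfigurationError("gaze must be finite")
    return sample_image(image, gaze[None, :] + sampler.offsets)


@dataclass
class SearchParams:
    """Tunables of the visual-search generative model.

    Times are in ms; precisions are spatial noise precisions.  The
    hypothesis states decay with the long time constant ``tau_h`` so that
    evidence accumulation is driven purely by precision-weighted
    prediction errors, not by intrinsic dynamics.
    """

    tau_o: float = 8.0           # oculomotor attraction time constant (ms)
    tau_h: float = 1e5           # hypothesis log-propensity leak (ms); the
                                 # stimulus is constant within a trial, so the
                                 # leak is effectively absent and evidence
                                 # integrates across saccades
    info_rate: float = 1.0       # Fisher-information assimilation rate (1/ms)
    prop_precision: float = 2.0
    state_precision_o: float = 512.0
    state_precision_h: float = 64.0
    prior_precision: float = 16.0
    roughness: float = 1.0 / 32.0   # smooth noise (proprioception, states)
    roughness_vis: float = 1.0      # rough visual noise: little weight on
    order: int = 3                  # its velocity (saccadic suppression)

    def __post_init__(self) -> None:
        if self.tau_o <= 0 or self.tau_h <= 0:
            raise ConfigurationError("time constants must be positive")


def sensory_mapping_g(x: np.ndarray, hset: HypothesisSet,
                      sampler: FovealSampler) -> np.ndarray:
    """Visual + proprioceptive predictions from the hidden states.

    ``x = [x_o (2), x_h (K)]``; the visual part is the softmax-weighted
    mixture of the templates foveally sampled at the believed gaze, the
    proprioceptive part is the believed gaze itself.
    """
    x = np.asarray(x, dtype=float).reshape(-1)
    K = hset.K
    if x.size != 2 + K:
        raise ModelSpecificationError(f"expected {2 + K} hidden states, got {x.size}")
    x_o, x_h = x[:2], x[2:]
    w = softmax(x_h)
    samples = np.stack([foveal_sample(t, x_o, sampler) for t in hset.templates])
    vis = w @ samples
    return np.concatenate([vis, x_o])


def hidden_dynamics_f(x: np.ndarray, eta: np.ndarray, tau_o: float,
                      tau_h: float, K: int) -> np.ndarray:
    """State velocities: gaze drawn to the salient target, slow leak on x_h."""
    if tau_o <= 0 or tau_h <= 0:
        raise ConfigurationError("time constants must be positive")
    x = np.asarray(x, dtype=float).reshape(-1)
    x_o, x_h = x[:2], x[2 : 2 + K]
    eta = np.asarray(eta, dtype=float).reshape(2)
    return np.concatenate([(eta - x_o) / tau_o, -x_h / tau_h])


def make_search_model(hset: HypothesisSet, sampler: FovealSampler,
                      params: SearchParams | None = None) -> HierarchicalModel:
    """One-level generative model for the visual-search experiment.

    Hidden states: gaze (2) + hypothesis log-propensities (K); causes:
    the 2-D prior gaze attractor set from the salience map via
    ``model.set_prior``.
    """
    params = params or SearchParams()
    K = hset.K
    R = sampler.R

    def g(x, v):
        return sensory_mapping_g(x, hset, sampler)

    def jac_g(x, v, _h=1e-3):
        """Analytic mixture/softmax derivatives; image gradients by
        central differences at the bilinear-interpolation scale."""
        x_o, x_h = x[:2], x[2:]
        w = softmax(x_h)
        samples = np.stack([foveal_sample(t, x_o, sampler) for t in hset.templates])
        vis = w @ samples
        G = np.zeros((R, 2))
        for i in range(2):
            d = np.zeros(2)
            d[i] = _h
            sp = np.stack([foveal_sample(t, x_o + d, sampler) for t in hset.templates])
            sm = np.stack([foveal_sample(t, x_o - d, sampler) for t in hset.templates])
            G[:, i] = w @ (sp - sm) / (2 * _h)
        dvis_dh = np.stack([w[j] * (samples[j] - vis) for j in range(K)], axis=1)
        Jgx = np.zeros((R + 2, 2 + K))
        Jgx[:R, :2] = G
        Jgx[:R, 2:] = dvis_dh
        Jgx[R:, :2] = np.eye(2)
        return Jgx, np.zeros((R + 2, 2))

    def f(x, v):
        return hidden_dynamics_f(x, v, params.tau_o, params.tau_h, K)

    def jac_f(x, v):
        Jfx = np.zeros((2 + K, 2 + K))
        Jfx[:2, :2] = -np.eye(2) / params.tau_o
        Jfx[2:, 2:] = -np.eye(K) / params.tau_h
        Jfv = np.zeros((2 + K, 2))
        Jfv[:2, :2] = np.eye(2) / params.tau_o
        return Jfx, Jfv

    state_prec = np.concatenate([
        np.full(2, params.state_precision_o),
        np.full(K, params.state_precision_h),
    ])
    level = ModelLevel(
        ny=R + 2, nx=2 + K, nv=2, g=g, f=f, jac_g=jac_g, jac_f=jac_f,
        output_groups=[
            (np.arange(R), sampler.precision_profile, params.roughness_vis),
            (np.arange(R, R + 2), np.full(2, params.prop_precision), params.roughness),
        ],
        state_precision=state_prec,
        roughness_states=params.roughness,
    )
    return HierarchicalModel(
        [level], order=params.order,
        prior_mean=np.zeros(2),
        prior_precision=params.prior_precision,
        roughness_prior=params.roughness,
    )


class VisualWorld:
    """The physical side of the experiment: one true template and a gaze.

    Action is a gaze velocity command: ``advance`` integrates
    ``d(gaze)/dt = a``.  ``sense(t, a)`` returns generalised sensory data
    (order 0: foveal samples of the true template plus the proprioceptive
    gaze readout; order 1: the motion-induced rate of change of each
    channel, with the visual part obtained from the local image gradient;
    higher orders zero).
    """

    def __init__(self, hset: HypothesisSet, sampler: FovealSampler,
                 order: int = 3, gaze0=(0.0, 0.0), grad_step: float = 1e-3):
        self.hset = hset
        self.sampler = sampler
        self.order = int(order)
        self.gaze = np.asarray(gaze0, dtype=float).copy()
        self.grad_step = float(grad_step)
        self.true_template = hset.templates[hset.true_index]

    @property
    def ny(self) -> int:
        return self.sampler.R + 2

    def _image_gradient(self) -> np.ndarray:
        """d(samples)/d(gaze), shape (R, 2), by central differences."""
        h = self.grad_step
        G = np.zeros((self.sampler.R, 2))
        for i in range(2):
            d = np.zeros(2)
            d[i] = h
            sp = foveal_sample(self.true_template, self.gaze + d, self.sampler)
            sm = foveal_sample(self.true_template, self.gaze - d, self.sampler)
            G[:, i] = (sp - sm) / (2 * h)
        return G

    def sense(self, t: float, a: np.ndarray) -> np.ndarray:
        a = np.asarray(a, dtype=float).reshape(2)
        s = np.zeros((self.order, self.ny))
        s[0, : self.sampler.R] = foveal_sample(self.true_template, self.gaze, self.sampler)
        s[0, self.sampler.R :] = self.gaze
        if self.order > 1:
            s[1, : self.sampler.R] = self._image_gradient() @ a
            s[1, self.sampler.R :] = a
        return s

    __call__ = sense

    def advance(self, dt: float, a: np.ndarray) -> None:
        self.gaze = self.gaze + dt * np.asarray(a, dtype=float).reshape(2)


def world_sensory_source(hset: HypothesisSet, sampler: FovealSampler,
                         order: int = 3, gaze0=(0.0, 0.0)) -> VisualWorld:
    """Factory for the action-controlled world sensory source."""
    return VisualWorld(hset, sampler, order=order, gaze0=gaze0)
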
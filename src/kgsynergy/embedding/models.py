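"""Scoring functions and analytic gradients for five KG-embedding models.

Each model maps a triple (h, r, t) to a real plausibility score (higher =
more plausible).  Score forms:

* TransE   : -||h + r - t||_2                (translation in R^d)
* TransR   : -||M_r h + r - M_r t||_2^2      (relation-specific projection)
* RotatE   : -||h o r - t||_2                (rotation in C^d, |r_i| = 1)
* ComplEx  : Re(sum_i h_i r_i conj(t_i))     (complex bilinear)
* HolE     : r . (h star t)                  (circular correlation,
             [a star b]_k = sum_i a_i b_{(i+k) mod d})

Complex quantities are stored as paired real arrays; the circular
correlation is evaluated via the FFT, with the O(d^2) double loop kept as
an independent oracle for tests.  Gradients are derived by hand and
verified against finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "MODEL_REGISTRY",
    "get_model",
    "circular_correlation_naive",
    "circular_correlation",
]

_EPS = 1e-12


def circular_correlation(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Circular correlation along the last axis, via the FFT."""
    return np.fft.ifft(np.conj(np.fft.fft(a, axis=-1)) * np.fft.fft(b, axis=-1), axis=-1).real


def circular_correlation_naive(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """O(d^2) double-loop circular correlation (test oracle)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    d = a.shape[-1]
    out = np.zeros_like(a)
    for k in range(d):
        for i in range(d):
            out[..., k] += a[..., i] * b[..., (i + k) % d]
    return out


def _circular_convolution(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return np.fft.ifft(np.fft.fft(a, axis=-1) * np.fft.fft(b, axis=-1), axis=-1).real


class _ModelBase:
    """Interface: parameter init, batched scoring, batched backward pass."""

    name: str = ""
    default_loss: str = "margin_ranking"

    def init_params(
        self, n_entities: int, n_relations: int, dim: int, rng: np.random.Generator
    ) -> dict[str, np.ndarray]:
        raise NotImplementedError

    def score(
        self, params: dict[str, np.ndarray], h: np.ndarray, r: np.ndarray, t: np.ndarray
    ) -> np.ndarray:
        """Scores for index arrays h, r, t of equal length."""
        raise NotImplementedError

    def backward(
        self,
        params: dict[str, np.ndarray],
        h: np.ndarray,
        r: np.ndarray,
        t: np.ndarray,
        upstream: np.ndarray,
        grads: dict[str, np.ndarray],
    ) -> None:
        """Accumulate d(upstream . score)/d(params) into dense ``grads``."""
        raise NotImplementedError

    def apply_constraints(self, params: dict[str, np.ndarray]) -> None:
        """Re-apply model-specific parameter constraints (in place)."""

    def entity_vectors(self, params: dict[str, np.ndarray]) -> np.ndarray:
        """Real-valued per-entity embedding matrix (complex models return
        the concatenation of real and imaginary parts)."""
        raise NotImplementedError


def _scaled_normal(rng, shape, dim):
    return rng.normal(0.0, 1.0 / np.sqrt(dim), size=shape)


class TransE(_ModelBase):
    name = "TransE"
    default_loss = "margin_ranking"

    def __init__(self, normalize_entities: bool = True):
        self.normalize_entities = normalize_entities

    def init_params(self, n_entities, n_relations, dim, rng):
        params = {
            "ent": _scaled_normal(rng, (n_entities, dim), dim),
            "rel": _scaled_normal(rng, (n_relations, dim), dim),
        }
        self.apply_constraints(params)
        return params

    def score(self, params, h, r, t):
        diff = params["ent"][h] + params["rel"][r] - params["ent"][t]
        return -np.sqrt(np.sum(diff * diff, axis=-1) + _EPS)

    def backward(self, params, h, r, t, upstream, grads):
        diff = params["ent"][h] + params["rel"][r] - params["ent"][t]
        norm = np.sqrt(np.sum(diff * diff, axis=-1) + _EPS)
        g = (-upstream / norm)[:, None] * diff
        np.add.at(grads["ent"], h, g)
        np.add.at(grads["rel"], r, g)
        np.add.at(grads["ent"], t, -g)

    def apply_constraints(self, params):
        if self.normalize_entities:
            norms = np.linalg.norm(params["ent"], axis=-1, keepdims=True)
            params["ent"] /= np.maximum(norms, _EPS)

    def entity_vectors(self, params):
        return params["ent"]


class TransR(_ModelBase):
    name = "TransR"
    default_loss = "margin_ranking"

    def init_params(self, n_entities, n_relations, dim, rng):
        # projection matrices start near identity so early training behaves
        # like TransE before relation-specific spaces differentiate
        proj = np.tile(np.eye(dim), (n_relations, 1, 1))
        proj += rng.normal(0.0, 0.05, size=proj.shape)
        return {
            "ent": _scaled_normal(rng, (n_entities, dim), dim),
            "rel": _scaled_normal(rng, (n_relations, dim), dim),
            "proj": proj,
        }

    def _residual(self, params, h, r, t):
        M = params["proj"][r]  # (B, d, d)
        hd = params["ent"][h] - params["ent"][t]  # (B, d)
        return np.einsum("bij,bj->bi", M, hd) + params["rel"][r]

    def score(self, params, h, r, t):
        u = self._residual(params, h, r, t)
        return -np.sum(u * u, axis=-1)

    def backward(self, params, h, r, t, upstream, grads):
        M = params["proj"][r]
        hd = params["ent"][h] - params["ent"][t]
        u = np.einsum("bij,bj->bi", M, hd) + params["rel"][r]
        du = (-2.0 * upstream)[:, None] * u  # (B, d)
        dent = np.einsum("bij,bi->bj", M, du)  # M^T du
        np.add.at(grads["ent"], h, dent)
        np.add.at(grads["ent"], t, -dent)
        np.add.at(grads["rel"], r, du)
        np.add.at(grads["proj"], r, np.einsum("bi,bj->bij", du, hd))

    def entity_vectors(self, params):
        return params["ent"]


class RotatE(_ModelBase):
    name = "RotatE"
    default_loss = "margin_ranking"

    def init_params(self, n_entities, n_relations, dim, rng):
        return {
            "ent_re": _scaled_normal(rng, (n_entities, dim), dim),
            "ent_im": _scaled_normal(rng, (n_entities, dim), dim),
            "phase": rng.uniform(0.0, 2.0 * np.pi, size=(n_relations, dim)),
        }

    def _diff(self, params, h, r, t):
        c, s = np.cos(params["phase"][r]), np.sin(params["phase"][r])
        h_re, h_im = params["ent_re"][h], params["ent_im"][h]
        d_re = h_re * c - h_im * s - params["ent_re"][t]
        d_im = h_re * s + h_im * c - params["ent_im"][t]
        return c, s, h_re, h_im, d_re, d_im

    def score(self, params, h, r, t):
        *_, d_re, d_im = self._diff(params, h, r, t)
        return -np.sqrt(np.sum(d_re * d_re + d_im * d_im, axis=-1) + _EPS)

    def backward(self, params, h, r, t, upstream, grads):
        c, s, h_re, h_im, d_re, d_im = self._diff(params, h, r, t)
        norm = np.sqrt(np.sum(d_re * d_re + d_im * d_im, axis=-1) + _EPS)
        scale = (-upstream / norm)[:, None]
        dd_re, dd_im = scale * d_re, scale * d_im
        np.add.at(grads["ent_re"], h, dd_re * c + dd_im * s)
        np.add.at(grads["ent_im"], h, -dd_re * s + dd_im * c)
        np.add.at(grads["ent_re"], t, -dd_re)
        np.add.at(grads["ent_im"], t, -dd_im)
        dphase = dd_re * (-h_re * s - h_im * c) + dd_im * (h_re * c - h_im * s)
        np.add.at(grads["phase"], r, dphase)

    def apply_constraints(self, params):
        # phases parameterize unit-modulus rotations by construction; keep
        # them wrapped for numerical hygiene only
        np.mod(params["phase"], 2.0 * np.pi, out=params["phase"])

    def entity_vectors(self, params):
        return np.concatenate([params["ent_re"], params["ent_im"]], axis=-1)


class ComplEx(_ModelBase):
    name = "ComplEx"
    default_loss = "softplus"

    def init_params(self, n_entities, n_relations, dim, rng):
        return {
            "ent_re": _scaled_normal(rng, (n_entities, dim), dim),
            "ent_im": _scaled_normal(rng, (n_entities, dim), dim),
            "rel_re": _scaled_normal(rng, (n_relations, dim), dim),
            "rel_im": _scaled_normal(rng, (n_relations, dim), dim),
        }

    def score(self, params, h, r, t):
        h_re, h_im = params["ent_re"][h], params["ent_im"][h]
        r_re, r_im = params["rel_re"][r], params["rel_im"][r]
        t_re, t_im = params["ent_re"][t], params["ent_im"][t]
        return np.sum(
            h_re * r_re * t_re + h_im * r_re * t_im + h_re * r_im * t_im - h_im * r_im * t_re,
            axis=-1,
        )

    def backward(self, params, h, r, t, upstream, grads):
        u = upstream[:, None]
        h_re, h_im = params["ent_re"][h], params["ent_im"][h]
        r_re, r_im = params["rel_re"][r], params["rel_im"][r]
        t_re, t_im = params["ent_re"][t], params["ent_im"][t]
        np.add.at(grads["ent_re"], h, u * (r_re * t_re + r_im * t_im))
        np.add.at(grads["ent_im"], h, u * (r_re * t_im - r_im * t_re))
        np.add.at(grads["rel_re"], r, u * (h_re * t_re + h_im * t_im))
        np.add.at(grads["rel_im"], r, u * (h_re * t_im - h_im * t_re))
        np.add.at(grads["ent_re"], t, u * (h_re * r_re - h_im * r_im))
        np.add.at(grads["ent_im"], t, u * (h_im * r_re + h_re * r_im))

    def entity_vectors(self, params):
        return np.concatenate([params["ent_re"], params["ent_im"]], axis=-1)


class HolE(_ModelBase):
    name = "HolE"
    default_loss = "softplus"

    def init_params(self, n_entities, n_relations, dim, rng):
        return {
            "ent": _scaled_normal(rng, (n_entities, dim), dim),
            "rel": _scaled_normal(rng, (n_relations, dim), dim),
        }

    def score(self, params, h, r, t):
        corr = circular_correlation(params["ent"][h], params["ent"][t])
        return np.sum(params["rel"][r] * corr, axis=-1)

    def backward(self, params, h, r, t, upstream, grads):
        u = upstream[:, None]
        eh, et, er = params["ent"][h], params["ent"][t], params["rel"][r]
        np.add.at(grads["rel"], r, u * circular_correlation(eh, et))
        np.add.at(grads["ent"], h, u * circular_correlation(er, et))
        np.add.at(grads["ent"], t, u * _circular_convolution(eh, er))

    def entity_vectors(self, params):
        return params["ent"]


MODEL_REGISTRY: dict[str, type[_ModelBase]] = {
    m.name: m for m in (TransE, TransR, RotatE, ComplEx, HolE)
}


def get_model(name: str) -> _ModelBase:
    try:
        return MODEL_REGISTRY[name]()
    except KeyError:
        raise ValueError(
            f"unknown model {name!r}; choose from {sorted(MODEL_REGISTRY)}"
        ) from None
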
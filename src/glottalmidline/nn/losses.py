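"""Training losses for keypoint regression and segmentation.

The keypoint losses (MAE, MSE, log-cosh, Huber) operate on coordinate
vectors; the Dice loss operates on segmentation maps with +1 smoothing
in both numerator and denominator:

    Dice(y, yhat) = 1 - (2 * sum(y * yhat) + 1) / (sum(y) + sum(yhat) + 1)

Note log-cosh is a sum (not mean) over components.
"""

from __future__ import annotations

from .autodiff import Tensor

__all__ = ["mae", "mse", "logcosh", "huber", "dice", "LOSSES", "get_loss"]


def _lift(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def mae(y, yhat) -> Tensor:
    y, yhat = _lift(y), _lift(yhat)
    return (y - yhat).abs().mean()


def mse(y, yhat) -> Tensor:
    y, yhat = _lift(y), _lift(yhat)
    return ((y - yhat) ** 2).mean()


def logcosh(y, yhat) -> Tensor:
    y, yhat = _lift(y), _lift(yhat)
    return (y - yhat).logcosh().sum()


def huber(y, yhat, delta: float = 1.0) -> Tensor:
    """Quadratic within |r| <= delta, linear (delta*|r| - delta^2/2) outside.

    Summed over components like the piecewise definition; the branch is
    selected per component.
    """
    y, yhat = _lift(y), _lift(yhat)
    r = y - yhat
    quad_mask = (abs(r.data) <= delta).astype(float)
    quad = (r ** 2) * 0.5
    lin = r.abs() * delta - 0.5 * delta ** 2
    return (quad * Tensor(quad_mask) + lin * Tensor(1.0 - quad_mask)).sum()


def dice(y, yhat) -> Tensor:
    y, yhat = _lift(y), _lift(yhat)
    inter = (y * yhat).sum()
    return 1.0 - (2.0 * inter + 1.0) / (y.sum() + yhat.sum() + 1.0)


LOSSES = {"mae": mae, "mse": mse, "logcosh": logcosh, "huber": huber,
          "dice": dice}


def get_loss(name: str):
    try:
        return LOSSES[name]
    except KeyError:
        raise ValueError(f"unknown loss {name!r}; choose from {sorted(LOSSES)}")
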
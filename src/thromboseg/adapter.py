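"""Optional adapter contract for plugging the losses into a two-stage detector.

A Mask R-CNN-style host framework exposes replaceable loss hooks: the
bounding-box regression loss is swapped for the combined smooth-L1 + CIoU
loss, the mask loss for the weighted binary focal loss, and classification
stays plain cross-entropy.  The adapter builds tensor-native closures for
those hooks when torch is importable and reports its unavailability
cleanly otherwise — the rest of the library has no torch dependency.
"""

from __future__ import annotations

import importlib.util
import math
from typing import Callable

__all__ = [
    "HOOK_NAMES",
    "AdapterUnavailableError",
    "torch_available",
    "MaskRCNNLossHooks",
    "build_loss_hooks",
]

#: the replaceable loss hooks of a two-stage detection head
HOOK_NAMES = ("box_regression", "mask", "classification")


class AdapterUnavailableError(ImportError):
    """Raised when the host detection framework (torch) is not installed."""


def torch_available() -> bool:
    return importlib.util.find_spec("torch") is not None


class MaskRCNNLossHooks:
    """Named registry of loss callables for a detection head.

    Unknown hook names are rejected with the list of valid ones, and the
    configuration is echoed by :meth:`describe` so training logs can
    record exactly which losses and hyper-parameters were plugged in.
    """

    def __init__(self, hooks: dict[str, Callable], config: dict[str, float]):
        unknown = set(hooks) - set(HOOK_NAMES)
        if unknown:
            raise ValueError(
                f"unknown loss hook(s) {sorted(unknown)}; valid hooks are {list(HOOK_NAMES)}"
            )
        self._hooks = dict(hooks)
        self.config = dict(config)

    def __getitem__(self, name: str) -> Callable:
        if name not in HOOK_NAMES:
            raise KeyError(
                f"unknown loss hook {name!r}; valid hooks are {list(HOOK_NAMES)}"
            )
        return self._hooks[name]

    def __contains__(self, name: str) -> bool:
        return name in self._hooks

    def describe(self) -> str:
        params = ", ".join(f"{k}={v}" for k, v in sorted(self.config.items()))
        return f"MaskRCNNLossHooks(box_regression=sciou, mask=weighted_focal, classification=cross_entropy; {params})"


def build_loss_hooks(
    delta: float = 0.2,
    lam: float = 2.0,
    gamma: float = 2.0,
    image_size: float = 512.0,
    eps: float = 1e-7,
) -> MaskRCNNLossHooks:
    """Build torch-tensor loss hooks for a Mask R-CNN-style head.

    Requires torch; raises :class:`AdapterUnavailableError` with an
    explicit message when it is absent so that pipelines can fall back or
    fail loudly at configuration time rather than mid-training.
    """
    if not (0.0 <= delta <= 1.0):
        raise ValueError("delta must lie in [0, 1]")
    if lam < 0 or gamma < 0:
        raise ValueError("lam and gamma must be >= 0")
    if not torch_available():
        raise AdapterUnavailableError(
            "the detector adapter requires torch/torchvision, which are not "
            "installed; the library's losses, metrics and harness work without them"
        )
    import torch

    def box_regression(pred: "torch.Tensor", target: "torch.Tensor") -> "torch.Tensor":
        """Batched sciou loss on (N, 4) corner tensors; mean reduction."""
        p, t = pred, target
        scale = p.new_tensor([image_size, image_size, image_size, image_size])
        r = (p - t) / scale
        sl1 = torch.where(r.abs() < 1, 0.5 * r * r, r.abs() - 0.5).sum(dim=1)

        ix1 = torch.maximum(p[:, 0], t[:, 0])
        iy1 = torch.maximum(p[:, 1], t[:, 1])
        ix2 = torch.minimum(p[:, 2], t[:, 2])
        iy2 = torch.minimum(p[:, 3], t[:, 3])
        inter = (ix2 - ix1).clamp(min=0) * (iy2 - iy1).clamp(min=0)
        area_p = (p[:, 2] - p[:, 0]) * (p[:, 3] - p[:, 1])
        area_t = (t[:, 2] - t[:, 0]) * (t[:, 3] - t[:, 1])
        union = area_p + area_t - inter
        iou = inter / union.clamp(min=eps)

        ew = torch.maximum(p[:, 2], t[:, 2]) - torch.minimum(p[:, 0], t[:, 0])
        eh = torch.maximum(p[:, 3], t[:, 3]) - torch.minimum(p[:, 1], t[:, 1])
        c_sq = (ew * ew + eh * eh).clamp(min=eps)
        dx = (p[:, 0] + p[:, 2] - t[:, 0] - t[:, 2]) / 2
        dy = (p[:, 1] + p[:, 3] - t[:, 1] - t[:, 3]) / 2
        rho_sq = dx * dx + dy * dy

        w = (p[:, 2] - p[:, 0]).clamp(min=eps)
        h = (p[:, 3] - p[:, 1]).clamp(min=eps)
        wt = (t[:, 2] - t[:, 0]).clamp(min=eps)
        ht = (t[:, 3] - t[:, 1]).clamp(min=eps)
        v = (4 / math.pi**2) * (torch.atan(wt / ht) - torch.atan(w / h)) ** 2
        alpha = v / ((1 - iou) + v).clamp(min=eps)
        ciou = 1 - iou + rho_sq / c_sq + alpha * v
        return (delta * sl1 + (1 - delta) * ciou).mean()

    def mask(pred: "torch.Tensor", target: "torch.Tensor") -> "torch.Tensor":
        """Weighted binary focal loss on (N, m, m) probability tensors."""
        pr = pred.clamp(eps, 1 - eps)
        zeta = target.to(pr.dtype)
        pos = -zeta * (1 - pr) ** gamma * torch.log(pr)
        neg = -(1 - zeta) * pr**gamma * torch.log(1 - pr)
        return (lam * pos + neg).mean()

    def classification(logits: "torch.Tensor", labels: "torch.Tensor") -> "torch.Tensor":
        return torch.nn.functional.cross_entropy(logits, labels)

    return MaskRCNNLossHooks(
        hooks={
            "box_regression": box_regression,
            "mask": mask,
            "classification": classification,
        },
        config={"delta": delta, "lam": lam, "gamma": gamma, "image_size": image_size},
    )
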
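"""Supervised contrastive training on labeled domain families.

Domains carry four-level hierarchical classification labels
(class.fold.superfamily.family, SCOPe-sccs style). Training pulls
embeddings of same-family domains together and pushes different
families apart.

Batch scheme: each epoch cycles over the training families in shuffled
order. For each anchor family, five other families are drawn at random;
for each of the six families, six member domains are drawn (without
replacement until the family is exhausted, then duplicates fill up to
six). The 36 domains with six unique labels form one batch, and one
optimizer step is taken per batch.

Augmentation: during training only, zero-mean Gaussian noise of variance
1.0 Å² is added independently to every Cα coordinate component before
featurization. Noise is resampled each time a domain appears, so
duplicated family members are not bit-identical inputs.

The loss is the multi-positive supervised contrastive loss in its
"positives averaged outside the log" form with temperature 0.1. The
optimizer is Adam (learning rate 5e-5, weight decay 1e-16 by default).
After every epoch the family-level retrieval sensitivity is computed on
the validation set (validation domains as both queries and database,
self-hit included) and the checkpoint from the best epoch is returned.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ._nn import Adam
from .features import featurize
from .model import GraphBatch, Model, ModelConfig, init_model
from .structure_io import DomainStructure

logger = logging.getLogger(__name__)

__all__ = [
    "ClassificationLabel",
    "TrainingConfig",
    "LabeledDomain",
    "sample_batch",
    "add_coordinate_noise",
    "supervised_contrastive_loss",
    "train",
]


@dataclass(frozen=True)
class ClassificationLabel:
    """Hierarchical fold classification code, e.g. ``a.1.1.2``:
    class.fold.superfamily.family. Equality at a deeper level implies
    equality at all shallower levels."""

    class_id: str
    fold_id: str
    superfamily_id: str
    family_id: str

    @classmethod
    def parse(cls, code: str) -> "ClassificationLabel":
        parts = code.strip().split(".")
        if len(parts) != 4 or not all(parts):
            raise ValueError(f"expected class.fold.superfamily.family, got {code!r}")
        return cls(*parts)

    def __str__(self) -> str:
        return ".".join(
            (self.class_id, self.fold_id, self.superfamily_id, self.family_id)
        )

    # hierarchical comparisons ------------------------------------------

    def fold_key(self) -> tuple[str, str]:
        return (self.class_id, self.fold_id)

    def superfamily_key(self) -> tuple[str, str, str]:
        return (self.class_id, self.fold_id, self.superfamily_id)

    def family_key(self) -> tuple[str, str, str, str]:
        return (self.class_id, self.fold_id, self.superfamily_id, self.family_id)

    def same_fold(self, other: "ClassificationLabel") -> bool:
        return self.fold_key() == other.fold_key()

    def same_superfamily(self, other: "ClassificationLabel") -> bool:
        return self.superfamily_key() == other.superfamily_key()

    def same_family(self, other: "ClassificationLabel") -> bool:
        return self.family_key() == other.family_key()


@dataclass(frozen=True)
class TrainingConfig:
    temperature: float = 0.1
    families_per_batch: int = 6
    domains_per_family: int = 6
    noise_variance: float = 1.0  # Å² per coordinate component
    learning_rate: float = 5e-5
    weight_decay: float = 1e-16
    max_epochs: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")
        if self.families_per_batch < 2 or self.domains_per_family < 2:
            raise ValueError("need >= 2 families and >= 2 domains per family")
        if self.noise_variance < 0:
            raise ValueError("noise_variance must be >= 0")


@dataclass
class LabeledDomain:
    """One training/benchmark item: a domain plus its classification."""

    domain_id: str
    structure: DomainStructure
    label: ClassificationLabel


def group_by_family(
    domains: list[LabeledDomain],
) -> dict[tuple[str, str, str, str], list[LabeledDomain]]:
    families: dict[tuple[str, str, str, str], list[LabeledDomain]] = {}
    for item in domains:
        families.setdefault(item.label.family_key(), []).append(item)
    return families


def _draw_members(
    members: list[LabeledDomain], k: int, rng: np.random.Generator
) -> list[LabeledDomain]:
    """k members, without replacement until the family is exhausted, then
    random duplicates fill up to k."""
    if len(members) >= k:
        idx = rng.choice(len(members), size=k, replace=False)
    else:
        extra = rng.choice(len(members), size=k - len(members), replace=True)
        idx = np.concatenate([np.arange(len(members)), extra])
    return [members[i] for i in idx]


def sample_batch(
    families: dict[tuple[str, str, str, str], list[LabeledDomain]],
    anchor_family: tuple[str, str, str, str],
    rng: np.random.Generator,
    families_per_batch: int = 6,
    domains_per_family: int = 6,
) -> list[LabeledDomain]:
    """One contrastive batch: the anchor family plus ``families_per_batch
    − 1`` random other families, ``domains_per_family`` members each
    (36 items with 6 unique labels at the defaults)."""
    if len(families) < families_per_batch:
        raise ValueError(
            f"need >= {families_per_batch} families, have {len(families)}"
        )
    if anchor_family not in families:
        raise KeyError(f"unknown anchor family {anchor_family}")
    others = sorted(k for k in families if k != anchor_family)
    chosen_idx = rng.choice(len(others), size=families_per_batch - 1, replace=False)
    chosen = [anchor_family] + [others[i] for i in chosen_idx]
    batch: list[LabeledDomain] = []
    for key in chosen:
        batch.extend(_draw_members(families[key], domains_per_family, rng))
    return batch


def add_coordinate_noise(
    coords: np.ndarray, variance: float, rng: np.random.Generator
) -> np.ndarray:
    """Independent zero-mean Gaussian noise of the given variance (Å²)
    added to every coordinate component. Training-time augmentation only;
    never applied at inference."""
    if variance < 0:
        raise ValueError("variance must be >= 0")
    if variance == 0:
        return np.array(coords, dtype=float, copy=True)
    return coords + rng.normal(0.0, np.sqrt(variance), size=np.shape(coords))


def supervised_contrastive_loss(
    embeddings: np.ndarray,
    labels: list,
    temperature: float = 0.1,
    return_grad: bool = False,
):
    """Multi-positive supervised contrastive loss (positives averaged
    outside the log).

    For each anchor i with positive set P(i) (same label, excluding i):

        L_i = −(1/|P(i)|) Σ_{p∈P(i)} log( exp(z_i·z_p/τ) /
                                          Σ_{a≠i} exp(z_i·z_a/τ) )

    and the loss is the mean of L_i over anchors. Every anchor must have
    at least one positive. With ``return_grad`` the analytic gradient
    with respect to the embeddings is also returned.
    """
    z = np.asarray(embeddings, dtype=float)
    n = len(z)
    same = np.array(
        [[labels[i] == labels[j] for j in range(n)] for i in range(n)]
    )
    positives = same & ~np.eye(n, dtype=bool)
    n_pos = positives.sum(axis=1)
    if np.any(n_pos == 0):
        raise ValueError("every anchor needs at least one same-label positive")

    sim = z @ z.T / temperature
    np.fill_diagonal(sim, -np.inf)
    row_max = sim.max(axis=1, keepdims=True)
    exp_sim = np.exp(sim - row_max)
    denom = exp_sim.sum(axis=1, keepdims=True)
    log_prob = sim - row_max - np.log(denom)  # log softmax over a ≠ i
    pos_log_prob = np.where(positives, log_prob, 0.0)  # mask the -inf diagonal
    loss = float(np.mean(-pos_log_prob.sum(axis=1) / n_pos))
    if not return_grad:
        return loss

    softmax = exp_sim / denom
    softmax[~np.isfinite(softmax)] = 0.0
    grad_sim = (softmax - positives / n_pos[:, None]) / n
    grad_sim[np.eye(n, dtype=bool)] = 0.0
    grad_z = (grad_sim @ z + grad_sim.T @ z) / temperature
    return loss, grad_z


@dataclass
class EpochRecord:
    epoch: int
    mean_loss: float
    val_family_sensitivity: float


def _validation_family_sensitivity(model: Model, items: list[LabeledDomain]) -> float:
    """Family-level sensitivity with the validation set as its own search
    database (self-hit included)."""
    from .evaluation import sensitivity_up_to_first_fp  # circular-safe

    graphs = [featurize(it.structure) for it in items]
    z = model.forward(GraphBatch(graphs))
    labels = [it.label for it in items]
    sims = z @ z.T
    total = 0.0
    for i in range(len(items)):
        order = np.argsort(-sims[i], kind="stable")
        ranked = [labels[j] for j in order]
        n_tp = sum(labels[i].same_family(lab) for lab in labels)
        total += sensitivity_up_to_first_fp(ranked, labels[i], "family", n_tp)
    return total / len(items)


def train(
    train_set: list[LabeledDomain],
    validation_set: list[LabeledDomain],
    model_config: ModelConfig | None = None,
    training_config: TrainingConfig | None = None,
) -> tuple[Model, list[EpochRecord]]:
    """Train a model on ``train_set`` and return the checkpoint from the
    epoch with the best validation family sensitivity, plus the per-epoch
    history.

    One optimizer step is taken per anchor family per epoch; family order
    is shuffled each epoch (seeded).
    """
    if not train_set or not validation_set:
        raise ValueError("train and validation sets must be non-empty")
    cfg = training_config or TrainingConfig()
    model = init_model(model_config)
    families = group_by_family(train_set)
    if len(families) < cfg.families_per_batch:
        raise ValueError(
            f"need >= {cfg.families_per_batch} training families, "
            f"have {len(families)}"
        )
    rng = np.random.default_rng(cfg.seed)
    optimizer = Adam(
        list(model.parameters()),
        lr=cfg.learning_rate,
        weight_decay=cfg.weight_decay,
    )
    family_keys = sorted(families)
    history: list[EpochRecord] = []
    best_sensitivity = -1.0
    best_state = model.copy_state()

    for epoch in range(1, cfg.max_epochs + 1):
        order = rng.permutation(len(family_keys))
        losses = []
        for idx in order:
            batch_items = sample_batch(
                families,
                family_keys[idx],
                rng,
                cfg.families_per_batch,
                cfg.domains_per_family,
            )
            graphs = []
            for item in batch_items:
                noisy = item.structure
                coords = add_coordinate_noise(
                    noisy.ca_coords, cfg.noise_variance, rng
                )
                graphs.append(
                    featurize(
                        DomainStructure(
                            name=noisy.name,
                            ca_coords=coords,
                            residue_numbers=noisy.residue_numbers,
                        )
                    )
                )
            z = model.forward(GraphBatch(graphs))
            loss, grad_z = supervised_contrastive_loss(
                z,
                [item.label.family_key() for item in batch_items],
                cfg.temperature,
                return_grad=True,
            )
            optimizer.zero_grad()
            model.backward(grad_z)
            optimizer.step()
            losses.append(loss)

        sensitivity = _validation_family_sensitivity(model, validation_set)
        history.append(EpochRecord(epoch, float(np.mean(losses)), sensitivity))
        logger.info(
            "epoch %d: loss %.4f, validation family sensitivity %.3f",
            epoch,
            history[-1].mean_loss,
            sensitivity,
        )
        # ties favour the later epoch: a small validation set saturates
        # quickly while the loss is still decreasing
        if sensitivity >= best_sensitivity:
            best_sensitivity = sensitivity
            best_state = model.copy_state()

    model.load_state_arrays(best_state)
    return model, history
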
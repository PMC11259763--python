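"""Logistic regression trained entirely on ciphertext.

Mirrors :mod:`helr.lr` operation-for-operation: the same NAG lookahead
update, the same ridge penalty, the same polynomial sigmoid and the same
seed-driven batch order, so ciphertext/plaintext parity is directly
testable.  All arithmetic goes through the public Evaluator surface; the
secret key appears only in :func:`decrypt_weights` and inside the refresh
authority.

Packing layout: rows are assigned once to consecutive blocks of
``batch_size`` (matching the plaintext trainer's fixed blocks); each block
stores one ciphertext per design-matrix column holding that block's column
values in the leading slots (padding slots are zero, so padded rows carry
zero weight in every gradient sum), plus one ciphertext for the outcomes.
Weights and momenta are kept in broadcast form — one ciphertext per
coefficient with the scalar replicated across slots — so the batch-sized
slotwise products need no weight rotations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .he import (
    CiphertextVector,
    Evaluator,
    HEContext,
    KeyMismatchError,
    KeyPair,
    PublicKey,
    RefreshAuthority,
    SlotCapacityError,
    encrypt,
    decrypt,
)
from .lr import (
    ModelWeights,
    TrainConfig,
    batch_blocks,
    epoch_block_order,
    fit_poly_sigmoid,
)
from .preprocess import DesignMatrix

__all__ = [
    "PackedMatrix",
    "EncryptedWeights",
    "pack_dataset",
    "merge_encrypted",
    "train_encrypted",
    "decrypt_weights",
    "iteration_depth",
    "predicted_refresh_count",
]


@dataclass
class _Block:
    cols: list[CiphertextVector]      # one ciphertext per column
    y: CiphertextVector
    mask: np.ndarray                  # plaintext 0/1 row-validity mask
    n_real: int


@dataclass
class PackedMatrix:
    """Encrypted design matrix in batch-major blocks."""

    blocks: list[_Block]
    columns: list[str]
    sites: list[str]
    batch_size: int
    context: HEContext
    public_key: PublicKey
    evaluator: Evaluator

    @property
    def n(self) -> int:
        return sum(b.n_real for b in self.blocks)

    def block_index_arrays(self) -> list[np.ndarray]:
        """Row-index arrays (into the concatenated row order) matching this
        pack's block layout — lets the plaintext mirror consume batches in
        exactly the same composition after a merge."""
        out, start = [], 0
        for b in self.blocks:
            out.append(np.arange(start, start + b.n_real))
            start += b.n_real
        return out


@dataclass
class EncryptedWeights:
    """Single ciphertext holding the coefficients in slots 0..p-1 and the
    intercept in slot p."""

    ciphertext: CiphertextVector
    columns: list[str]

    @property
    def level(self) -> int:
        return self.ciphertext.level

    @property
    def scale(self) -> float:
        return self.ciphertext.scale


def pack_dataset(matrix: DesignMatrix, context: HEContext, keys: KeyPair,
                 batch_size: int = 64) -> PackedMatrix:
    """Encrypt a design matrix block by block (deterministic layout)."""
    if matrix.p + 1 > context.slots:
        raise SlotCapacityError(
            f"p={matrix.p} exceeds slot capacity {context.slots}"
        )
    if batch_size > context.slots:
        raise SlotCapacityError("batch_size exceeds slot capacity")
    evaluator = Evaluator(keys.public_key, keys.relin_key, keys.rotation_key)
    blocks = []
    for idx in batch_blocks(matrix.n, batch_size):
        m = len(idx)
        cols = []
        for j in range(matrix.p):
            vec = np.zeros(batch_size)
            vec[:m] = matrix.X[idx, j]
            cols.append(encrypt(vec, keys.public_key))
        yvec = np.zeros(batch_size)
        yvec[:m] = matrix.y[idx]
        mask = np.zeros(batch_size)
        mask[:m] = 1.0
        blocks.append(_Block(cols, encrypt(yvec, keys.public_key), mask, m))
    return PackedMatrix(blocks, list(matrix.columns),
                        list(np.asarray(matrix.site, dtype=str)),
                        batch_size, context, keys.public_key, evaluator)


def merge_encrypted(packs: list[PackedMatrix]) -> PackedMatrix:
    """Concatenate packed datasets without any decryption.

    All packs must share the column schema, context and keypair.
    """
    if not packs:
        raise ValueError("nothing to merge")
    head = packs[0]
    for p in packs[1:]:
        if p.columns != head.columns:
            raise ValueError("schema mismatch between packs")
        if p.context is not head.context:
            raise ValueError("context mismatch between packs")
        if p.public_key.key_id != head.public_key.key_id:
            raise KeyMismatchError("packs encrypted under different keys")
        if p.batch_size != head.batch_size:
            raise ValueError("batch size mismatch between packs")
    blocks = [b for p in packs for b in p.blocks]
    sites = [s for p in packs for s in p.sites]
    return PackedMatrix(blocks, list(head.columns), sites, head.batch_size,
                        head.context, head.public_key, head.evaluator)


def iteration_depth(poly_degree: int) -> int:
    """Ciphertext-multiply depth of one NAG iteration: one for the linear
    predictor, (degree - 1) for the sigmoid polynomial powers, one for the
    residual-by-feature gradient products."""
    return poly_degree + 1


def predicted_refresh_count(n_blocks: int, epochs: int, p: int,
                            poly_degree: int, level_budget: int) -> int:
    """Refreshes the depth schedule implies: weight and velocity ciphertexts
    (p + 1 each) are refreshed at the start of every iteration whose inputs
    sit below ``iteration_depth + 1``; with the default budget that is every
    iteration after the first."""
    total_iters = n_blocks * epochs
    if total_iters == 0:
        return 0
    need = iteration_depth(poly_degree) + 1
    per_iter_drop = iteration_depth(poly_degree)
    refreshed_iters = total_iters - 1 if level_budget - per_iter_drop < need \
        else 0
    return 2 * (p + 1) * refreshed_iters


def train_encrypted(pack: PackedMatrix, config: TrainConfig,
                    context: HEContext,
                    authority: RefreshAuthority) -> EncryptedWeights:
    """Run the NAG/poly-sigmoid/ridge training loop on ciphertext.

    Epochs are fixed (no encrypted early stopping: the loss cannot be
    inspected without decryption).  Only the public operation surface plus
    the refresh authority is used.
    """
    if config.sigmoid_mode != "poly":
        raise ValueError(
            "encrypted training requires sigmoid_mode='poly'; the exact "
            "sigmoid is not ciphertext-evaluable"
        )
    ev = pack.evaluator
    pk = pack.public_key
    p = len(pack.columns)
    poly = fit_poly_sigmoid(config.poly_degree)
    coeffs = poly.coeffs
    mu, lr, lam = config.momentum, config.learning_rate, config.l2_lambda
    need_level = iteration_depth(config.poly_degree) + 1

    zeros = np.zeros(context.slots)
    W = [encrypt(zeros, pk) for _ in range(p + 1)]   # broadcast form
    V = [encrypt(zeros, pk) for _ in range(p + 1)]

    def ensure_level(ct: CiphertextVector) -> CiphertextVector:
        if ct.level < need_level:
            return authority.refresh(ct)
        return ct

    n_blocks = len(pack.blocks)
    for epoch in range(config.epochs):
        for bi in epoch_block_order(n_blocks, epoch, config.seed):
            block = pack.blocks[bi]
            W = [ensure_level(ct) for ct in W]
            V = [ensure_level(ct) for ct in V]

            # lookahead point w + mu*v (linear; no level cost)
            look = [ev.add(W[j], ev.mul_plain(V[j], mu))
                    for j in range(p + 1)]

            # linear predictor z = sum_j x_j * la_j + la_intercept
            z = ev.mul(block.cols[0], look[0])
            for j in range(1, p):
                z = ev.add(z, ev.mul(block.cols[j], look[j]))
            z = ev.add(z, look[p])

            # polynomial sigmoid: powers z^2..z^degree then linear combo
            powers = [z]
            for _ in range(config.poly_degree - 1):
                powers.append(ev.mul(powers[-1], z))
            prob = ev.mul_plain(powers[0], coeffs[1])
            for k in range(2, config.poly_degree + 1):
                if coeffs[k] != 0.0:
                    prob = ev.add(prob, ev.mul_plain(powers[k - 1], coeffs[k]))
            prob = ev.add_plain(prob, coeffs[0])

            resid = ev.sub(prob, block.y)
            inv_m = 1.0 / block.n_real

            # gradient per coefficient: sum over rows of resid * x_j
            # (padding slots of x_j are zero, so padded rows drop out);
            # the intercept uses the explicit padding mask.
            grads = []
            for j in range(p):
                g = ev.slot_sum(ev.mul(resid, block.cols[j]))
                g = ev.mul_plain(g, inv_m)
                if lam != 0.0:
                    g = ev.add(g, ev.mul_plain(look[j], lam))
                grads.append(g)
            g_int = ev.mul_plain(
                ev.slot_sum(ev.mul_plain(resid, block.mask)), inv_m
            )
            grads.append(g_int)

            # NAG update: v <- mu*v - lr*g ; w <- w + v
            V = [ev.sub(ev.mul_plain(V[j], mu), ev.mul_plain(grads[j], lr))
                 for j in range(p + 1)]
            W = [ev.add(W[j], V[j]) for j in range(p + 1)]

    # repack broadcast weights into a single ciphertext: slot j <- w_j
    unit = np.zeros(context.slots)
    unit[0] = 1.0
    acc = ev.mul_plain(W[0], unit)
    for j in range(1, p + 1):
        e_j = np.zeros(context.slots)
        e_j[j] = 1.0
        acc = ev.add(acc, ev.mul_plain(W[j], e_j))
    acc.slot_len = p + 1
    return EncryptedWeights(acc, list(pack.columns))


def decrypt_weights(enc: EncryptedWeights, sk) -> ModelWeights:
    """Decrypt an encrypted weight vector into lr_core's schema."""
    if enc.ciphertext.key_id != sk.key_id:
        raise KeyMismatchError("weights encrypted under a different key")
    values = decrypt(enc.ciphertext, sk)
    p = len(enc.columns)
    if len(values) < p + 1 or not np.isfinite(values[: p + 1]).all():
        raise ValueError("decryption produced an invalid weight vector "
                         "(key mismatch?)")
    return ModelWeights(values[:p], float(values[p]), list(enc.columns))
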
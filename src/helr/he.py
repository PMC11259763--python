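"""CKKS-style leveled homomorphic arithmetic: a contract plus a toy
reference backend.

The backend models approximate slot arithmetic on real vectors with:

* a fixed scale ``Delta`` — every payload value is quantized to the
  ``1/Delta`` grid, so each operation introduces a bounded rounding error;
* randomized encryption noise, so two encryptions of the same vector differ;
* level bookkeeping — each ciphertext-by-ciphertext multiply (with
  relinearization and rescale) consumes one level, and arithmetic below
  level zero raises; plaintext multiplies fold their constants into the
  encoding and do not consume a level in this model;
* key binding — decryption with the wrong secret key yields garbage;
* a deterministic, monotone per-ciphertext ``noise_bound`` in payload units.

This is a correctness- and contract-faithful simulation of the computation,
NOT a cryptosystem: secrecy is enforced at the API level (training code only
ever sees the public operation surface; audited in tests), not by lattice
hardness.  A production adapter to an established FHE library can be
substituted behind the same contract.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "HEContext",
    "KeyPair",
    "PublicKey",
    "SecretKey",
    "CiphertextVector",
    "Evaluator",
    "RefreshAuthority",
    "keygen",
    "encrypt",
    "decrypt",
    "HEError",
    "LevelExhaustionError",
    "ScaleMismatchError",
    "KeyMismatchError",
    "SlotCapacityError",
]


class HEError(RuntimeError):
    pass


class LevelExhaustionError(HEError):
    pass


class ScaleMismatchError(HEError):
    pass


class KeyMismatchError(HEError):
    pass


class SlotCapacityError(HEError):
    pass


@dataclass
class HEContext:
    """Arithmetic parameters and operation meters.

    ``ring_dim`` is the ring dimension N (power of two); the backend packs
    N/2 real slots per ciphertext.  ``scale`` is the CKKS-style scale Delta;
    quantization to the 1/Delta grid is the error model's granularity.
    ``level_budget`` is the number of ct-by-ct multiplies a fresh ciphertext
    supports before it must be refreshed.
    """

    ring_dim: int = 2 ** 13
    scale: float = float(2 ** 40)
    level_budget: int = 6
    noise_units: float = 3.2          # fresh-encryption noise sd, grid units
    noise_seed: int = 0               # seeds the simulated noise stream
    counters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        # one noise stream per context: successive encryptions differ, but a
        # rerun from an identically-constructed context is reproducible
        self._noise_rng = np.random.default_rng(
            [self.noise_seed, self.ring_dim, self.level_budget]
        )
        if self.ring_dim < 2 or self.ring_dim & (self.ring_dim - 1):
            raise ValueError("ring_dim must be a power of two >= 2")
        if self.scale <= 1:
            raise ValueError("scale must exceed 1")
        if self.level_budget < 1:
            raise ValueError("level_budget must be >= 1")
        for key in ("encrypt", "decrypt", "add", "add_plain", "mul_plain",
                    "mul", "rotate", "refresh"):
            self.counters.setdefault(key, 0)

    @property
    def slots(self) -> int:
        return self.ring_dim // 2

    @property
    def quantum(self) -> float:
        """Grid step of the quantized arithmetic (1/Delta)."""
        return 1.0 / self.scale

    def fresh_noise_bound(self) -> float:
        # rounding half-step plus a 6-sigma bound on the encryption noise
        return (0.5 + 6.0 * self.noise_units) * self.quantum

    def meter(self, op: str) -> None:
        self.counters[op] = self.counters.get(op, 0) + 1


@dataclass(frozen=True)
class PublicKey:
    key_id: str
    key_bytes: bytes
    context: HEContext


@dataclass(frozen=True)
class SecretKey:
    key_id: str
    _seed: int
    context: HEContext


@dataclass(frozen=True)
class EvalKey:
    """Opaque relinearization / rotation key material."""
    key_id: str
    kind: str


@dataclass(frozen=True)
class KeyPair:
    public_key: PublicKey
    secret_key: SecretKey
    relin_key: EvalKey
    rotation_key: EvalKey


def keygen(context: HEContext, seed: int) -> KeyPair:
    """Deterministic keypair bound to the context parameters."""
    if not isinstance(context, HEContext):
        raise ValueError("invalid context")
    rng = np.random.default_rng([seed, context.ring_dim,
                                 int(context.level_budget)])
    sk_seed = int(rng.integers(0, 2 ** 62))
    digest = hashlib.sha256(
        f"{sk_seed}:{context.ring_dim}:{context.scale}".encode()
    )
    key_id = digest.hexdigest()[:16]
    pk = PublicKey(key_id, digest.digest(), context)
    sk = SecretKey(key_id, sk_seed, context)
    return KeyPair(pk, sk,
                   EvalKey(key_id, "relin"), EvalKey(key_id, "rotation"))


@dataclass
class CiphertextVector:
    """Opaque encrypted slot vector with level/scale/noise bookkeeping."""

    _payload: np.ndarray
    level: int
    scale: float
    slot_len: int
    key_id: str
    noise_bound: float

    def __repr__(self) -> str:  # payload deliberately not shown
        return (f"CiphertextVector(level={self.level}, scale={self.scale:g}, "
                f"slots={self.slot_len}, noise_bound={self.noise_bound:.3e})")


def _quantize(v: np.ndarray, context: HEContext) -> np.ndarray:
    return np.round(v * context.scale) / context.scale


def encrypt(v: np.ndarray, pk: PublicKey) -> CiphertextVector:
    """Encrypt a real slot vector (randomized; length <= slot count)."""
    context = pk.context
    v = np.asarray(v, dtype=float).ravel()
    if v.size > context.slots:
        raise SlotCapacityError(
            f"vector of length {v.size} exceeds {context.slots} slots"
        )
    slots = np.zeros(context.slots)
    slots[: v.size] = v
    noise = context._noise_rng.normal(
        0.0, context.noise_units * context.quantum, context.slots
    )
    payload = _quantize(slots, context) + noise
    context.meter("encrypt")
    return CiphertextVector(payload, context.level_budget, context.scale,
                            v.size, pk.key_id, context.fresh_noise_bound())


def decrypt(ct: CiphertextVector, sk: SecretKey) -> np.ndarray:
    """Decrypt; a wrong key yields garbage far outside the error bound."""
    sk.context.meter("decrypt")
    if ct.key_id != sk.key_id:
        bad = np.random.default_rng(
            abs(hash((ct.key_id, sk.key_id))) % (2 ** 63)
        )
        return bad.uniform(-1e6, 1e6, ct.slot_len)
    return ct._payload[: ct.slot_len].copy()


class Evaluator:
    """Public-surface homomorphic operations.

    Constructed from public material only (public key + evaluation keys);
    never sees the secret key.
    """

    def __init__(self, pk: PublicKey, relin_key: EvalKey,
                 rotation_key: EvalKey):
        if relin_key.key_id != pk.key_id or rotation_key.key_id != pk.key_id:
            raise KeyMismatchError("evaluation keys not bound to public key")
        self.pk = pk
        self.context = pk.context
        self._relin = relin_key
        self._rot = rotation_key

    # -- helpers ----------------------------------------------------------

    def _check_pair(self, a: CiphertextVector, b: CiphertextVector) -> None:
        if a.key_id != b.key_id:
            raise KeyMismatchError("operands encrypted under different keys")
        if abs(a.scale - b.scale) > 1e-9 * a.scale:
            raise ScaleMismatchError(
                f"scale mismatch: {a.scale:g} vs {b.scale:g}"
            )

    def _encode(self, v) -> np.ndarray:
        arr = np.asarray(v, dtype=float)
        if arr.ndim == 0:
            return np.full(self.context.slots, float(arr))
        if arr.size > self.context.slots:
            raise SlotCapacityError("plaintext operand exceeds slot count")
        out = np.zeros(self.context.slots)
        out[: arr.size] = arr.ravel()
        return out

    # -- operations -------------------------------------------------------

    def add(self, a: CiphertextVector, b: CiphertextVector) -> CiphertextVector:
        self._check_pair(a, b)
        self.context.meter("add")
        return CiphertextVector(a._payload + b._payload,
                                min(a.level, b.level), a.scale,
                                max(a.slot_len, b.slot_len), a.key_id,
                                a.noise_bound + b.noise_bound)

    def sub(self, a: CiphertextVector, b: CiphertextVector) -> CiphertextVector:
        return self.add(a, self.neg(b))

    def neg(self, a: CiphertextVector) -> CiphertextVector:
        return CiphertextVector(-a._payload, a.level, a.scale, a.slot_len,
                                a.key_id, a.noise_bound)

    def add_plain(self, a: CiphertextVector, v) -> CiphertextVector:
        self.context.meter("add_plain")
        enc = _quantize(self._encode(v), self.context)
        return CiphertextVector(a._payload + enc, a.level, a.scale,
                                a.slot_len or self.context.slots, a.key_id,
                                a.noise_bound + 0.5 * self.context.quantum)

    def mul_plain(self, a: CiphertextVector, v) -> CiphertextVector:
        """Multiply by a plaintext vector/scalar.  Constants are folded into
        the encoding in this model, so no level is consumed; the payload is
        re-quantized to the grid."""
        self.context.meter("mul_plain")
        enc = self._encode(v)
        payload = _quantize(a._payload * enc, self.context)
        amp = float(np.max(np.abs(enc))) if enc.size else 0.0
        return CiphertextVector(
            payload, a.level, a.scale, a.slot_len, a.key_id,
            a.noise_bound * max(amp, 1e-300) + 0.5 * self.context.quantum,
        )

    def mul(self, a: CiphertextVector, b: CiphertextVector) -> CiphertextVector:
        """Ciphertext multiply with relinearization and rescale; consumes one
        level from min(level_a, level_b)."""
        self._check_pair(a, b)
        if self._relin is None:
            raise HEError("relinearization key required")
        out_level = min(a.level, b.level) - 1
        if out_level < 0:
            raise LevelExhaustionError(
                "level budget exhausted; refresh required"
            )
        self.context.meter("mul")
        payload = _quantize(a._payload * b._payload, self.context)
        mag_a = float(np.max(np.abs(a._payload)))
        mag_b = float(np.max(np.abs(b._payload)))
        bound = (a.noise_bound * mag_b + b.noise_bound * mag_a
                 + a.noise_bound * b.noise_bound + 0.5 * self.context.quantum)
        return CiphertextVector(payload, out_level, a.scale,
                                max(a.slot_len, b.slot_len), a.key_id, bound)

    def rotate(self, a: CiphertextVector, k: int) -> CiphertextVector:
        """Cyclic left shift of the slot vector by k (over all slots)."""
        if self._rot is None:
            raise HEError("rotation key required")
        self.context.meter("rotate")
        return CiphertextVector(np.roll(a._payload, -k), a.level, a.scale,
                                self.context.slots, a.key_id, a.noise_bound)

    def slot_sum(self, a: CiphertextVector) -> CiphertextVector:
        """Rotate-and-add reduction leaving the total of all slots in every
        slot (log2(slots) rotations; costs no level)."""
        acc = a
        shift = 1
        while shift < self.context.slots:
            acc = self.add(acc, self.rotate(acc, shift))
            shift *= 2
        return acc


class RefreshAuthority:
    """Privileged handle that restores a ciphertext's level budget.

    Functional stand-in for CKKS bootstrapping: the reference backend
    decrypts and re-encrypts under the same key.  The only component besides
    final decryption allowed to touch the secret key; every refresh is
    counted.
    """

    def __init__(self, keypair: KeyPair):
        self._sk = keypair.secret_key
        self._pk = keypair.public_key
        self.refresh_count = 0

    def refresh(self, ct: CiphertextVector) -> CiphertextVector:
        if ct.key_id != self._sk.key_id:
            raise KeyMismatchError("authority not authorized for this key")
        context = self._pk.context
        values = ct._payload.copy()
        noise = context._noise_rng.normal(
            0.0, context.noise_units * context.quantum, context.slots
        )
        payload = _quantize(values, context) + noise
        self.refresh_count += 1
        context.meter("refresh")
        return CiphertextVector(payload, context.level_budget, context.scale,
                                ct.slot_len, ct.key_id,
                                ct.noise_bound + context.fresh_noise_bound())
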
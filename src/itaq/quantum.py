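"""Noiseless statevector engine for the variational quantum circuit.

The circuit is the "basic entangling" ansatz used by the hybrid regressor:

* angle embedding: ``RX(x_q)`` on every qubit of ``|0...0>``;
* ``L`` entangling layers, each a trainable ``RX(theta_{l,q})`` on every
  qubit followed by a ring of CNOTs ``q -> (q+1) mod n`` (for a single
  qubit there is no entangler; for two qubits a single CNOT, so the pair
  is not entangled and immediately disentangled);
* readout: Pauli-Z expectation value on every qubit.

States are dense complex vectors of length ``2**n`` (batched along the
leading axis).  The CNOT ring, being a permutation of basis states, is
pre-composed into a single index map, so each layer costs n RX sweeps
plus one gather.  Gradients with respect to both the embedding angles and
the layer parameters come from adjoint (reverse-mode) statevector
differentiation -- one backward sweep that un-applies each unitary --
and are exact to working precision.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "circuit_forward",
    "circuit_vjp",
    "simulate_circuit",
    "z_expectations",
]

_RING_PERMS: dict[int, tuple[np.ndarray, np.ndarray]] = {}
_ZSIGNS: dict[int, np.ndarray] = {}


def _zsigns(n: int) -> np.ndarray:
    """Matrix (n, 2**n) of Pauli-Z eigenvalue signs per qubit and basis state."""
    if n not in _ZSIGNS:
        k = np.arange(2**n)
        bits = (k[None, :] >> (n - 1 - np.arange(n)[:, None])) & 1
        _ZSIGNS[n] = 1.0 - 2.0 * bits
    return _ZSIGNS[n]


def _ring_pairs(n: int) -> list[tuple[int, int]]:
    if n == 1:
        return []
    if n == 2:
        return [(0, 1)]
    return [(q, (q + 1) % n) for q in range(n)]


def _ring_perm(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Composed basis permutation of the CNOT ring and its inverse.

    ``state_after = state_before[..., perm]``.
    """
    if n not in _RING_PERMS:
        k = np.arange(2**n)
        for control, target in _ring_pairs(n):
            cbit = (k >> (n - 1 - control)) & 1
            k = np.where(cbit == 1, k ^ (1 << (n - 1 - target)), k)
        # k[i] = source index contributing to output i after the full ring?
        # Built forward: applying gate G to amplitudes means out[G(i)] = in[i];
        # equivalently out = in[perm] with perm = argsort of the image map.
        image = k
        perm = np.empty_like(image)
        perm[image] = np.arange(2**n)
        inv = image
        _RING_PERMS[n] = (perm, inv)
    return _RING_PERMS[n]


def _apply_rx(state: np.ndarray, q: int, theta, n: int) -> np.ndarray:
    """RX(theta) on qubit ``q``; ``theta`` is scalar or per-batch (B,)."""
    B = state.shape[0]
    s = state.reshape(B, 2**q, 2, 2 ** (n - q - 1))
    th = np.asarray(theta, dtype=state.real.dtype)
    c = np.cos(th / 2.0)
    sn = np.sin(th / 2.0)
    if th.ndim == 1:  # per-sample angle
        c = c[:, None, None]
        sn = sn[:, None, None]
    a, b = s[:, :, 0, :], s[:, :, 1, :]
    out = np.empty_like(s)
    out[:, :, 0, :] = c * a - 1j * sn * b
    out[:, :, 1, :] = -1j * sn * a + c * b
    return out.reshape(B, -1)


def _rx_grad(lam: np.ndarray, psi: np.ndarray, q: int, n: int) -> np.ndarray:
    """Per-sample Im <lam| X_q |psi> without materialising X_q psi."""
    B = lam.shape[0]
    l4 = lam.reshape(B, 2**q, 2, 2 ** (n - q - 1))
    p4 = psi.reshape(B, 2**q, 2, 2 ** (n - q - 1))
    acc = np.einsum("blr,blr->b", np.conj(l4[:, :, 0, :]), p4[:, :, 1, :])
    acc += np.einsum("blr,blr->b", np.conj(l4[:, :, 1, :]), p4[:, :, 0, :])
    return acc.imag


def z_expectations(state: np.ndarray, n: int) -> np.ndarray:
    """Per-qubit <Z> of a batch of states, shape (B, n)."""
    probs = np.abs(state) ** 2
    return probs @ _zsigns(n).T


def circuit_forward(
    angles: np.ndarray,
    params: np.ndarray,
    return_state: bool = False,
    dtype=np.complex128,
):
    """Run the embedding + entangling circuit.

    Parameters
    ----------
    angles
        (B, n) per-sample embedding angles.
    params
        (L, n) trainable layer rotation angles.
    dtype
        Statevector precision; single precision roughly halves the cost of
        training sweeps at ~1e-7 accuracy.

    Returns the (B, n) Pauli-Z expectations (and the final statevector
    when ``return_state`` is set).
    """
    angles = np.atleast_2d(np.asarray(angles, dtype=float))
    params = np.asarray(params, dtype=float)
    if params.size == 0:
        params = params.reshape(0, angles.shape[1])
    if not (np.all(np.isfinite(angles)) and np.all(np.isfinite(params))):
        raise ValueError("circuit angles must be finite")
    B, n = angles.shape
    if params.ndim != 2 or params.shape[1] != n:
        raise ValueError(f"params must have shape (L, {n}), got {params.shape}")
    perm, _ = _ring_perm(n)
    state = np.zeros((B, 2**n), dtype=dtype)
    state[:, 0] = 1.0
    for q in range(n):
        state = _apply_rx(state, q, angles[:, q], n)
    for layer in params:
        for q in range(n):
            state = _apply_rx(state, q, layer[q], n)
        state = state[:, perm]
    z = z_expectations(state, n).astype(float)
    return (z, state) if return_state else z


def circuit_vjp(
    state: np.ndarray,
    angles: np.ndarray,
    params: np.ndarray,
    dz: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Adjoint-mode vector-Jacobian product of the circuit.

    Given the final ``state`` from :func:`circuit_forward` and the loss
    gradient ``dz`` with respect to the Z expectations, returns
    ``(d_angles, d_params)``: per-sample gradients for the embedding angles
    and batch-summed gradients for the layer parameters.
    """
    angles = np.atleast_2d(np.asarray(angles, dtype=float))
    dz = np.atleast_2d(np.asarray(dz, dtype=float))
    params = np.asarray(params, dtype=float)
    if params.size == 0:
        params = params.reshape(0, angles.shape[1])
    B, n = angles.shape
    L = params.shape[0]
    _, inv_perm = _ring_perm(n)

    psi = state
    lam = ((dz @ _zsigns(n)) * psi).astype(psi.dtype)  # H_eff |psi>

    d_params = np.zeros_like(params)
    d_angles = np.zeros_like(angles)

    for l in range(L - 1, -1, -1):
        psi = psi[:, inv_perm]
        lam = lam[:, inv_perm]
        for q in range(n - 1, -1, -1):
            d_params[l, q] = float(_rx_grad(lam, psi, q, n).sum())
            psi = _apply_rx(psi, q, -params[l, q], n)
            lam = _apply_rx(lam, q, -params[l, q], n)
    for q in range(n - 1, -1, -1):
        d_angles[:, q] = _rx_grad(lam, psi, q, n)
        psi = _apply_rx(psi, q, -angles[:, q], n)
        lam = _apply_rx(lam, q, -angles[:, q], n)
    return d_angles, d_params


def simulate_circuit(features: np.ndarray, params: np.ndarray) -> np.ndarray:
    """Z expectations of the circuit for a single feature vector.

    ``features`` are the post-encoder values fed to the angle embedding,
    one per qubit; ``params`` has shape (layers, qubits).
    """
    features = np.asarray(features, dtype=float)
    if features.ndim != 1:
        raise ValueError("features must be a 1-D vector (one angle per qubit)")
    return circuit_forward(features[None, :], np.asarray(params, dtype=float))[0]
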
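"""Independent dense-matrix circuit simulator used as a test oracle.

Builds explicit 2^n x 2^n gate matrices with Kronecker products — deliberately
naive and structurally unrelated to the package's statevector implementation.
Qubit 0 is the most significant bit of the basis index.
"""

import numpy as np


def op(n, q, m):
    mats = [np.eye(2)] * n
    mats[q] = m
    out = mats[0]
    for k in mats[1:]:
        out = np.kron(out, k)
    return out


def rz(t):
    return np.array([[np.exp(-1j * t / 2), 0], [0, np.exp(1j * t / 2)]])


def ry(t):
    return np.array([[np.cos(t / 2), -np.sin(t / 2)],
                     [np.sin(t / 2), np.cos(t / 2)]])


def cnot(n, cq, tq):
    u = np.zeros((2 ** n, 2 ** n), dtype=complex)
    for i in range(2 ** n):
        cb = (i >> (n - 1 - cq)) & 1
        u[i ^ (cb << (n - 1 - tq)), i] = 1
    return u


def run_circuit(state, angles, ranges):
    """Rot = RZ(a) then RY(b) then RZ(c) per qubit, then a CNOT ring."""
    depth, n, _ = angles.shape
    psi = state.astype(complex)
    for layer in range(depth):
        for q in range(n):
            a, b, c = angles[layer, q]
            psi = op(n, q, rz(c)) @ op(n, q, ry(b)) @ op(n, q, rz(a)) @ psi
        if n >= 2:
            for q in range(n):
                t = (q + ranges[layer]) % n
                if t != q:
                    psi = cnot(n, q, t) @ psi
    return psi
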
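"""Joint blind source separation of multiple datasets with IVA-G.

Builds K=4 synthetic datasets whose m-th sources are correlated across
datasets (each source component vector has its own planted correlation),
whitens each dataset, fits IVA-G by decoupled vector gradient descent, and
scores the result with the joint ISI (0 = the planted mixings were inverted
up to a shared permutation/scale, 1 = fully mixed).
"""

import numpy as np

from ivamotor import apply_whitening, fit_iva_g, fit_whitening, generate_jbss, joint_isi

K, M, N = 4, 6, 5000
rho = np.array([0.85, 0.70, 0.55, 0.40, 0.25, 0.10])
X, truth = generate_jbss(K=K, M=M, N=N, rho=rho, seed=2024)

V = [fit_whitening(Xk) for Xk in X]
Z = np.stack([apply_whitening(Vk, Xk) for Vk, Xk in zip(V, X)])

rng = np.random.default_rng(7)
best = None
for i in range(3):
    res = fit_iva_g(Z, rng.standard_normal((M, M)), mu=1.0, tol=1e-6, max_iter=256)
    isi = joint_isi(res, V, truth.A)
    print(f"initialisation {i}: joint ISI = {isi:.4f}, "
          f"cost {res.cost_trajectory[0]:.2f} -> {res.cost_trajectory[-1]:.2f}, "
          f"{res.n_iter} sweeps, converged={res.converged}")
    if best is None or isi < best[0]:
        best = (isi, res)

print(f"\nbest joint ISI: {best[0]:.4f}")
print("(below ~0.05 means the planted per-dataset mixings were recovered "
      "up to one shared permutation and per-component scaling)")
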
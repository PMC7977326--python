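"""Tune the model with cross-validation: component numbers, then sparsity.

Follows the two-stage procedure: a 2-D grid over the orthogonal component
numbers (Kx, Ky) at fixed K scored by joint-score cross-prediction, a
sequential search over K scored by cross-block prediction error, and a grid
over the numbers of retained groups (h_x, h_y) scored by held-out joint-score
covariance with the one-standard-error rule.
"""

from go2pls.model_selection import cv_joint, cv_orthogonal, cv_sparsity
from go2pls.simulation import scenario2_design, simulate_scenario2

design = scenario2_design(p=600, q=400, n_groups=40, n_relevant=8,
                          N=100, alpha=0.3, orth_ratio=2.0)
X, Y, truth = simulate_scenario2(design, seed=7)
print(f"data: X {X.data.shape}, Y {Y.data.shape}; "
      "generated with K=2, Kx=Ky=1, 8 relevant groups per component")

res_o = cv_orthogonal(X, Y, K_fixed=2, kx_grid=[0, 1, 2], ky_grid=[0, 1, 2],
                      folds=5, seed=0)
kx, ky = res_o.best_one_se["kx"], res_o.best_one_se["ky"]
print(f"orthogonal components: argmin {res_o.best}, one-SE choice "
      f"(kx={kx}, ky={ky})  <- fewest components within one SE")

res_k = cv_joint(X, Y, Kx=kx, Ky=ky, k_grid=[1, 2, 3, 4], folds=5, seed=0)
K = res_k.best_one_se["k"]
print(f"joint components: argmin {res_k.best}, one-SE choice K={K}")

res_h = cv_sparsity(X, Y, K=K, Kx=kx, Ky=ky,
                    hx_grid=[4, 8, 16, 32], hy_grid=[4, 8, 16],
                    groups_x=truth["groups_x"], groups_y=truth["groups_y"],
                    folds=5, seed=0)
print(f"sparsity: covariance maximiser {res_h.best}, "
      f"one-SE choice {res_h.best_one_se}")
print("summary table (head):")
print(res_h.summary_frame().head())
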
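# pbrecgi

Physiology-based regularization for the inverse problem of
electrocardiography, validated on synthetic torso–heart phantoms.

Electrocardiographic imaging (ECGI) reconstructs the electrical activity of
the heart surface from body-surface potential recordings and a torso–heart
geometry. In the potential-based formulation the forward problem is linear,

    Φ_B(t) = A Φ_H(t),

with Φ_H the epicardial potentials, Φ_B the body-surface potentials and A
the transfer matrix of the source-free homogeneous volume conductor between
the two surfaces. Inverting it is severely ill-posed: tiny measurement
noise produces wild, unphysiological solutions unless the inversion is
regularized. The classical remedy is Tikhonov regularization,

    min ‖A Φ_H(t) − Φ_B(t)‖² + λ(t) ‖R Φ_H(t)‖² ,

which penalizes solution amplitude (or smoothness) but knows nothing about
electrophysiology. This package implements an alternative: simulate many
propagating action potentials on the heart surface, decompose the stacked
patterns by SVD (Φ_H = U D Vᵀ), truncate the spatial basis to its leading
components (2–10 by default), and reconstruct the real potentials as a
*sparse* combination of those physiological building blocks,

    min ‖A U_k β(t) − Φ_B(t)‖²  subject to  ‖β(t)‖₁ ≤ λ(t),

solved independently per time instant (lasso in budget form), with Φ̂_H(t) =
U_k β(t). Downstream post-processing derives per-node activation/recovery
times (temporal and spatiotemporal criteria), localizes the pacing origin
at the earliest activation, and scores everything against ground truth.

The package is aimed at researchers studying ECGI regularization: it
contains the full chain — phantom geometries, a boundary-element forward
model with an analytic oracle, FitzHugh–Nagumo and Luo–Rudy 1991 cell
models on meshes, basis construction, both inverse solvers, timing maps and
the statistical evaluation — with no external data dependencies.

## Worked example

```python
import numpy as np
from pbrecgi import (ExperimentConfig, prepare_benchmark, run_benchmark)

art = prepare_benchmark(ExperimentConfig())   # phantom, beats, bases (~1 min)
rep = run_benchmark(artifacts=art)            # invert + score (~2 min)

for m in ("tikhonov", "pbr_all", "pbr_spec"):
    print(f"{m:9s} median CC {rep.median_cc(m):.3f}  "
          f"median R_rec {np.nanmedian(rep.r_rec[m]):.2f}  "
          f"median LE {np.median(rep.loc_err_st[m]):.1f} mm")
```

prints (seed 0, the default configuration):

```
tikhonov  median CC 0.893  median R_rec 0.96  median LE 22.3 mm
pbr_all   median CC 0.870  median R_rec 0.95  median LE 18.7 mm
pbr_spec  median CC 0.869  median R_rec 0.93  median LE 37.9 mm
```

Reading: per-electrode correlation between true and reconstructed
electrograms is high for every method at this noise level (30 dB), timing
maps are near ceiling once the timing detector's smoothing is applied, and
the sparse all-region basis combined with the spatiotemporal criterion
gives the best pacing-site localization (LE, on a 40 mm-radius heart). The
sparse method's accuracy is far less noise-sensitive than Tikhonov's (its
CC drops by ~0.03 from noiseless to 30 dB versus ~0.09 for Tikhonov), which
is the property the physiological basis buys. See `docs/methods.md` for
what the phantom can and cannot show — in particular why a perfectly known
geometry makes this Tikhonov baseline a best case.

A command-line interface mirrors the library for scripted runs
(`pbrecgi phantom / simulate / basis / invert / times / evaluate /
benchmark`); all artifacts live in a single HDF5 container per run.

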
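# eoflux

EOF-based fusion of gridded latent-heat-flux (LE) products.

Terrestrial latent heat flux — the energy carried off the land surface by
evapotranspiration, in W/m² — is mapped by several satellite-driven
algorithms (Penman–Monteith-based MOD16-style products, Priestley–Taylor
PT-JPL-style products). Individual products disagree, carry gaps and
product-specific bias, and ignore each other's strengths. `eoflux` merges
two co-registered space-time LE stacks into a single gap-free field by
mixing their empirical-orthogonal-function (EOF) components, for
researchers who need a consistent LE record for water- and carbon-cycle
analysis and want to validate it against eddy-covariance towers.

## Method

A space-time stack is a matrix **A** (P pixels × N steps). After per-row
mean removal it is factored by SVD,

    A = Z S Hᵀ,

where the columns of **Z** are spatial patterns (EOFs), the columns of
**H** temporal principal components, and the squared singular values the
variance per mode. To expose temporal lag structure, each pixel series is
first *delay-embedded* into a Hankel block of window length W (the
multichannel-SSA construction), blocks stacked vertically into a
(P·W) × (N−W+1) matrix; W = 1 recovers the plain EOF analysis.

The pipeline, per spatial tile (default 200 × 200 pixels):

1. **Gap filling (DINEOF).** Missing entries start at the removed-mean
   baseline and are iterated to the converged truncated-SVD
   reconstruction; observed entries are never touched.
2. **Decomposition.** Both products are delay-embedded (default W = 4)
   and decomposed.
3. **Component mixing.** The primary product keeps its leading modes up
   to 80% cumulative variance (k_a modes). The secondary contributes the
   modes at positions k_a+1 onward, up to a 20% variance share, capped at
   12 modes, added *without* its mean so the primary's climatology is not
   double-counted.
4. **Negative repair.** Truncated reconstruction can dip below zero in
   the low-flux season; negative cells take the secondary product's
   main-pattern value (or zero if that is negative too).

A constant-weight simple average (SA, weight 0.5) is provided as the
baseline fusion. Tower validation applies the Bowen-ratio-preserving
energy-balance closure correction

    LE = (Rn − G) / (LE_ori + H_ori) · LE_ori,

composites daily series to 8-day means, and reports R² (squared Pearson
correlation), bias and RMSE, pooled and per biome (CRO, DBF, DNF/ENF,
EBF, MF, SAW, SHR, GRA).

## Worked example

```sh
python examples/01_fuse_two_products.py
```

```
product A (primary, noisy):    RMSE =  11.15 W/m2
product B (secondary, gappy):  RMSE =   9.22 W/m2
simple average (weight 0.5):   RMSE =   8.02 W/m2
EOF fusion (W=4, 80/20):       RMSE =   7.05 W/m2
```

The benchmark generates a rank-3 seasonal truth field (40 × 40 grid, 46
eight-day steps) and two corrupted products: A with white retrieval noise
(sd 10 W/m², bias +5), B with structured truth-orthogonal noise (sd 9,
bias +2) and 10% gaps. The fused field beats both inputs and the
constant-weight average because truncation removes A's white noise while
B's complementary components restore the minor patterns truncation lost.
The other examples cover gap filling (`02`), tower validation with
closure correction (`03`) and tiled processing (`04`).

The same workflows are scriptable from the shell:

```sh
eoflux simulate --out-dir data --seed 5
eoflux fuse --product-a data/product_a.nc --product-b data/product_b.nc \
            --output data/fused.nc
eoflux validate --predicted data/fused.nc --towers data/towers.csv \
                --output data/metrics.csv
```

Every command writes a `manifest.json` (config, seed, version) next to
its outputs so a run can be replayed exactly.

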
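# fetoconn

Age-specific structural-connectome templates and developmental charts for
the fetal brain.

Between 22 and 37 gestational weeks the human structural connectome —
the weighted graph of white-matter connections between parcellated brain
regions — reorganizes rapidly: connection strengths grow, integration and
segregation metrics rise together, and a stable small-world topology is
maintained. `fetoconn` is a toolkit for charting that development from a
cohort of individual weighted connectomes (one symmetric, non-negative
adjacency matrix per subject, each with a gestational age). Raw diffusion
MRI processing is out of scope; the adjacency matrix is the unit of input.

## What it computes

**Age-specific templates by connectome aggregation.** Given subject
connectomes $C_s^i$ at ages $t_i$, the package estimates one template
$C_T^j$ per gestational week by minimizing

$$
L(C_T) \;=\; \underbrace{\sum_{i}\sum_{j} G(t_i,t_j)\,\lVert C_s^i - C_T^j\rVert_1}_{L_\text{repr}}
\;+\; \lambda_\text{cons} \underbrace{\sum_{j_1}\sum_{j_2} G(t_{j_1},t_{j_2})\,\lVert C_T^{j_1}-C_T^{j_2}\rVert_1}_{L_\text{cons}}
\;+\; \lambda_\text{dist} \underbrace{\sum_{i}\sum_{j} G(t_i,t_j)\, D_\text{JS}\!\big(p(C_s^i),\,p(C_T^j)\big)}_{L_\text{dist}}
$$

where $G(t_1,t_2)=\exp(-(t_1-t_2)^2/2\sigma^2)$ is a Gaussian age kernel
($\sigma = 1$ week), the $\ell_1$ matrix distance is the graph edit
distance for graphs with fixed nodes and weight-difference edit costs,
$p(C)$ is the 20-bin histogram of connection-weight mass as a function of
connection length, and $D_\text{JS}(p,q) = D_\text{KL}(p\|m) +
D_\text{KL}(q\|m)$ with $m=(p+q)/2$. The distance term counteracts the
short-range bias of consensus averaging so long-range connections are
proportionally preserved. The objective is minimized by stochastic
subgradient descent (learning rate $10^{-5}$) from per-week-average
initialization. Consensus-thresholded and distance-preserved averaging
baselines are included for comparison.

**Developmental trajectories.** Nodal strength is modeled with the
sigmoid growth curve $f(t) = b + L/(1+e^{-k(t-t_0)})$, whose inflection
point $t_0$ is the age of fastest growth; fits are bootstrapped (1000
draws of 75% of subjects, without replacement) for confidence bands and
inflection statistics, and compared against linear fits by adjusted R².
Edge-wise trends are screened by repeated subsampled regressions (100
repetitions, 95% retention rule), and nodal regressions by Bonferroni
correction.

**Graph metrics, hubs, evaluation, reproducibility.** Weighted global
and local efficiency, characteristic path length, Onnela clustering,
small-world index against degree-preserving rewired nulls, strength /
betweenness / eigenvector centralities with top-k hub extraction and hub
overlap; gestational-age prediction from templates (GED nearest-neighbor
and a linear-SVM same-age classifier with subject-level ten-fold CV);
split-half fingerprinting (intra- vs inter-subject GED).

**Synthetic cohorts.** A seeded generator produces bilateral node
tables, distance-dependent sparsity, per-edge sigmoid growth fields with
planted increasing/decreasing edges, and subject-level noise, so every
analysis is testable without any data download.

## Worked example

Fit a sigmoid growth model to a synthetic nodal-strength trajectory and
bootstrap its inflection point:

```python
import fetoconn as fc

ages, values = fc.sigmoid_node_samples(n=198, t0=28.6, seed=7)
res = fc.SigmoidGrowth(ages, values).fit()
print(res.summary())
ens = res.bootstrap(n_boot=1000, seed=7)
print(f"bootstrap t0: {ens.t0_mean:.2f} +/- {ens.t0_sd:.2f} weeks")
```

```
Sigmoid growth fit  f(t) = b + L / (1 + exp(-k (t - t0)))
==========================================================
n observations:   198
b  (baseline):    9.5067
L  (amplitude):   40.3551
k  (rate, 1/wk):  1.2445
t0 (inflection):  28.5519 weeks
slope at t0:      12.5557 per week
adj. R2 sigmoid:  0.9734
adj. R2 linear:   0.8356
converged:        True
bootstrap t0: 28.55 +/- 0.03 weeks
```

The generator planted its inflection at 28.6 weeks; the fit recovers it
within 0.05 weeks, the sigmoid clearly outperforms the linear model in
adjusted R², and the bootstrap spread shows the estimate is stable under
subject resampling.

Build weekly templates for a synthetic cohort (60 subjects, 30 regions):

```python
field, cohort, truth = fc.default_study()
model = fc.ConnectomeTemplateModel(cohort, weeks=range(22, 38))
res = model.fit(method="aggregate", seed=0)
print(res.summary())
```

```
Connectome template fit
===============================================
method:            aggregate
subjects:          60
nodes:             30
weeks:             22-37 (16 templates)
sigma (weeks):     1
lambda_cons:       1
lambda_dist:       1
-----------------------------------------------
L_repr:            8511.9728
L_cons:            972.9160
L_dist:            0.1947
total loss:        9485.0835
epochs run:        200
initial total:     9711.9557
```

The total loss decreased from 9712 to 9485 over 200 epochs;
`res.templates` holds the 16 weekly connectomes and
`res.loss_trace` / `res.plot_loss()` the per-epoch decomposition.

## Command line

```bash
fetoconn synth --d 88 --n 198 --seed 7 --out-dir synth/
fetoconn build-templates --manifest synth/manifest.tsv --nodes synth/nodes.tsv \
    --weeks 22:37 --seed 7 --out-dir templates/
fetoconn metrics --connectome synth/S001.csv --nulls 100 --seed 7 --out report.json
fetoconn trajectories --manifest synth/manifest.tsv --nodes synth/nodes.tsv --out traj.json
fetoconn edge-trends --manifest synth/manifest.tsv --reps 100 --out edges.tsv
fetoconn predict-age --manifest synth/manifest.tsv --templates templates/ --out pred.tsv
fetoconn run --config run.yaml        # full pipeline, stages configurable
```

Connectomes are square CSVs with node ids in the header row and first
column; cohorts are TSV manifests (`subject_id`, `age_weeks`,
`matrix_path`); node tables are TSVs with labels, hemisphere, lobe and
centroid coordinates in mm.

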
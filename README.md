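# unchosen

Simulation and analysis pipeline for studying **latent value updating of
unchosen actions** in a four-armed bandit task: task generation with
drifting reward probabilities, four Q-learning model variants, fully
Bayesian hierarchical fitting, leave-one-block-out model comparison, and
the model-independent lagged-trial regression signature.

## What's inside

| Module | Purpose |
| --- | --- |
| `unchosen.synthetic_task` | Task structure: bounded random-walk reward schedules, random two-of-four offers, win/loss payoff recoding, tidy trial CSV I/O |
| `unchosen.rl_models` | The four models — `baseline`, `double_two_pe`, `double_one_pe`, `select_reject` — with per-trial updates, softmax choice, sequence log-likelihoods and forward simulation |
| `unchosen.hierarchical_inference` | Non-centered hierarchical priors, logit/softplus transforms, NUTS fitting, posterior summaries (median / HDI95 / probability of direction), cohort parameter sampling |
| `unchosen.model_comparison` | Leave-one-block-out pointwise elpd and pairwise 2×SE comparison |
| `unchosen.sequential_analysis` | RT/no-response exclusions, the lagged-trial selection filter, raw rates, hierarchical Bayesian logistic regression with deliberation moderators, accuracy, individual-difference correlations |
| `unchosen.recovery_experiments` | Parameter recovery, model recovery, and signature-reproduction experiments as seeded recipes, plus a full-study runner |

Sampling is done by a self-contained No-U-Turn sampler
(`unchosen._nuts`) over analytic likelihood gradients compiled with
numba (`unchosen._likelihoods`) — no external probabilistic-programming
framework is required, and every run is exactly reproducible from its
seed.

## CLI

```bash
unchosen simulate --model select_reject --n-agents 40 --seed 1 --out trials.csv
unchosen fit      --model select_reject --data trials.csv --preset desk --out draws.csv
unchosen compare  --data trials.csv --models baseline,select_reject --out comparison.csv
unchosen analyze  --data trials.csv --lag 1 --moderators prev_difficulty --out signature.json
unchosen recover  params --model select_reject --n-agents 40 --out recovery.json
unchosen run-all  --seed 1 --out runs/full/
```

Trial CSVs use the columns `participant_id, block, block_type, trial,
offer_a, offer_b, choice, payoff, reward01, rt_ms` (`choice`/`rt_ms` may
be empty; `rt_ms` may be absent for simulated cohorts).

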
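# gatingrl

Reinforcement-learning **gating models of working memory**, applied to rule
learning in a rat maze task.

Rats learning a guided-turn maze rule ("turn the way you were guided" or
its opposite) need hundreds of trials to reach criterion. Gating models
explain such learning as a *multi-agent* RL problem: a **motor agent**
chooses the turn, and a **gating agent** decides at every step whether to
*update* a one-slot working memory with the current observation or
*maintain* its content. Both condition on the state s = (observation,
memory content) and learn by temporal difference with replacing eligibility
traces and softmax exploration,

    P(s, a) = exp(Q(s, a)/T) / sum_b exp(Q(s, b)/T),

with Actor-Critic (one critic error, delta = r + gamma V(s') - V(s)) or
SARSA (per-agent errors, delta_M = r + gamma Q^M(s',a') - Q^M(s,a))
updates, gamma = 1, learning rate alpha, trace decay lambda.

The package is for computational-neuroscience researchers who want to

- simulate the Actor-Critic, SARSA, and the bounded (AC-R) / no-trace-decay
  (SARSA-R) variants on the abstract maze with a configurable central-arm
  depth `n_central`;
- fit (alpha, T, lambda) per arm depth by minimizing the Gaussian KL
  divergence between the rats' sessions-to-criterion distribution
  ({17, 19, 20, 21, 22, 25}; mean 20.7, variance 7.5) and the model's
  simulated distribution, with multi-start Nelder-Mead;
- classify learned strategies (*remember-both* vs *remember-one*) and
  measure reversal transfer — SARSA and AC-R reacquire a reversed rule
  faster than they learned the original; plain Actor-Critic and SARSA-R do
  not.

See `docs/methods.md` for the full model description and design choices.

## Worked example

```python
import gatingrl as g

# 1,000 seeded SARSA runs at the published operating point
runs = g.simulate_runs(g.SARSA_BEST_FIT, 1000, g.SessionSchedule(), seed=11)
stc = [r.sessions_to_criterion for r in runs]
print(sum(stc) / len(stc))          # 23.616  sessions to criterion (rats: 20.7)

# classify the learned strategies of 100 runs
freq = g.strategy_frequencies(g.SARSA_BEST_FIT, n_runs=100, seed=17)
print(freq["remember_one_percent"])  # 47.0   % remembering only one side
print(freq["percentages"]["remember-both"])  # 52.0

# exact (enumeration, no sampling) value of a hand-coded strategy
motor, gating = g.remember_one_policy(rule="match")
print(g.evaluate_policy_exact(motor, gating, g.TaskConfig(n_central=3)))  # 1.0
```

The first number is the model's mean sessions-to-criterion under the
standard protocol (40-trial sessions; criterion = three consecutive
sessions at >= 85% correct), the quantity the published parameters were
fitted to match. The strategy percentages show that both models settle
into different but equally valid memory policies across runs — the last
line proves a "remember one side only" policy solves the task exactly.

The same analyses are available from the shell:

```
gatingrl simulate --variant sarsa --runs 1000 --seed 11 --out out/sim
gatingrl simulate --variant sarsa --runs 200 --reversal --seed 5 --out out/rev
gatingrl fit --variant ac --n-min 1 --n-max 8 --runs-per-eval 200 --out out/fit
gatingrl classify --variant ac --runs 100 --seed 17 --out out/cls
gatingrl gendata --variant sarsa --n-animals 6 --rat-fixture --out out/data
gatingrl report --run-dir out/rev
```

Each command writes CSV/JSON outputs plus a `manifest.json` (config echo,
seed, version, checksums); `report` re-renders the standard figures
(learning curves with +/-1 SD, KL vs n, transfer box plots, strategy
frequencies) from whatever outputs are present.

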
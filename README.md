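# hrlplan

Model-based **hierarchical reinforcement-learning planning** in gridworld
rooms domains: temporally abstract actions (options), option models,
saltatory planning, planning under working-memory failure, and
successor-representation subgoal discovery.

## The problem

A planning agent with an internal model of its environment can "imagine"
courses of action by simulating trajectories and improving its plan from the
projected outcomes.  Hierarchy changes the economics of this process.  An
**option** is a temporally extended action — an initiation set, an internal
policy, a termination function, and a pseudo-reward defining its subgoal —
that can be selected just like a primitive action.  An **option model**
summarises an option for planning: a joint distribution over termination
state and duration `k`, plus the expected discounted reward accrued during
execution.  With option models the planner can plan *saltatorily*: leap
straight to an option's predicted outcome, discounting by `γᵏ`, instead of
simulating each primitive step.

The package studies three tabular planners on the classic four-room
gridworld (104 cells, 4 doorways, step cost −1, γ = 0.95):

| agent | action set | transition machinery |
|---|---|---|
| flat | primitives | one-step model |
| hierarchical | primitives + doorway options | options executed step-by-step through the one-step model |
| saltatory | primitives + doorway options | option models: jump to the doorway, one decision |

Planning proceeds by ε-greedy trajectory sampling against the model with
SMDP Q-learning updates `Q(s,o) ← Q + α[R + γᵏ max Q(s′,·) − Q]`.  Two
phenomena are quantified:

* **Decision compression** — aggregating an `n`-action path into `m` options
  means the goal is reached after `m` independent choices; the package ships
  exact oracles for both the minimum primitive-step count (BFS) and the
  minimum decision count with option models.
* **Robustness to memory failure** — if every charged simulation step loses
  the agent's place with probability `p`, a plan of `n` decisions survives
  with probability `(1 − p)ⁿ`; shorter decision sequences are the mechanism
  by which option models keep planning alive under tight capacity limits.

Subgoal discovery closes the loop: a latent-learning agent that explores
reward-free, builds a transition model `T`, and computes the successor
representation `M = (I − γT)⁻¹` finds that clustering the rows of `M`
recovers the rooms, while the doorways stand out as poorly clustered
isolated points — natural subgoals for new options.

## Worked example

```bash
$ hrlplan oracle
min primitive steps: 20
min decisions with option models: 8
optimal value at start (gamma=0.95): -12.8303
```

From the start corner to the goal corner of the default map a shortest path
takes 20 primitive actions; chaining two doorway options plus six primitive
steps reaches the goal in 8 decisions.  The optimal discounted return from
the start, `−12.83`, is what a converged planner attains.

```bash
$ hrlplan sr
chosen clusters: 4; bottlenecks: [(2, 5), (4, 8), (5, 1), (9, 5)]
```

Silhouette-selected Ward clustering of successor-representation rows finds
exactly the four rooms, and the bottleneck rule returns exactly the four
doorway cells of the map.

```python
>>> from hrlplan import load_map, make_doorway_options, compute_option_model_exact
>>> world = load_map("rooms_default.map")
>>> opt = make_doorway_options(world)[0]        # upper-left room -> (2, 5)
>>> model = compute_option_model_exact(world, opt)
>>> model.outcome[(0, 0)]
{((2, 5), 7): 1.0}
>>> round(model.expected_reward[(0, 0)], 3)
-6.033
```

From the start cell this option terminates at doorway `(2, 5)` after 7
steps with certainty, accruing `Σₜ γᵗ·(−1) ≈ −6.03` along the way.

Experiments (CSV outputs, deterministic given `--seed`):

```bash
hrlplan experiment curves     --runs 100 --trials 100 --out results/
hrlplan experiment memory     --p-fail 0.1 --out results/
hrlplan experiment structure  --out results/
```

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the package's headline results from scratch on the default map —
the exact step/decision oracles, the three agents' smoothed learning
curves, memory-limited completion rates at `p_fail = 0.1`, and the
successor-representation cluster/bottleneck recovery — writing CSVs and the
results JSON under the output directory.

## Layout

* `hrlplan.envs` — ASCII map parsing, gridworld dynamics, BFS oracles,
  community graphs and random walks.
* `hrlplan.options` — doorway detection, option construction by value
  iteration on the pseudo-reward problem, exact (point-mass /
  absorbing-chain) and Monte-Carlo option models.
* `hrlplan.planners` — the three sample-based planners, SMDP value
  iteration, decision-count oracle, smoothing.
* `hrlplan.memory_limits` — the per-step failure protocol, survival law,
  counterfactual would-have-taken accounting.
* `hrlplan.sr_discovery` — successor representations, latent-learning
  transition estimation, clustering, bottleneck rule, classical MDS.
* `hrlplan.experiments` / `hrlplan.cli` — end-to-end experiments and the
  `hrlplan` command.

See `docs/methods.md` for modelling assumptions, parameter choices, and
known limitations.
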
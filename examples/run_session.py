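"""Run one full session with a human-like stochastic operator.

Builds a 5-minute, medium-demand configuration, closes the loop with the
stochastic operator model, and prints the whole-session performance
summary.  Scores are normalized 0-100 (higher is better, except
tracking_score / rm_tank*_score which are raw error percentages); the
workload columns are the operator's 1-10 subjective ratings and their
response latencies.
"""

from matbsim import SimulationConfig, StochasticOperator, run, summarize

config = SimulationConfig.model_validate({
    "duration": 300.0,
    "master_seed": 42,
    "demand": {"sysmon": 2, "comms": 2, "resman": 2},   # medium demand level
})
log = run(config, StochasticOperator(seed=7))

summary = summarize(log).set_index("section").loc["session"]
print(f"rows logged: {len(log.samples)} ticks at {config.tick_dt} s")
for col in ("sysmon_score", "sysmon_accuracy", "comms_score", "comms_accuracy",
            "tracking_score", "tracking_performance",
            "rm_tank1_score", "rm_tank2_score", "workload_value", "workload_rt"):
    print(f"{col:>22}: {summary[col]:8.2f}")
print("\nA mean sysmon_score near 57 reflects ~1.5 s response latencies (which")
print("alone would score ~70/100 against the 5 s timeout) pulled down by the")
print("few missed lights that score 0; rm scores near 0 would mean the main")
print("tanks were held right at the 2,000-unit target.")
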
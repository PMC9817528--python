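"""Validate a gait labeller against a judge panel.

Simulates a five-bout ride with four judges who click 0.2-0.6 s after
each real transition (one of them briefly disagreeing), aggregates their
labels every 250 ms by strict plurality, summarises the labeller's event
log on a 1 s / 0.5 s sliding window, pairs the two series into test
cases, and prints agreement for growing transition-exclusion radii.
"""

import equigait as eg

plan = eg.RidePlan(
    bouts=[
        eg.Bout(eg.Gait.WALK, 25.0),
        eg.Bout(eg.Gait.TOLT, 25.0),
        eg.Bout(eg.Gait.TROT, 25.0),
        eg.Bout(eg.Gait.CANTER, 25.0),
        eg.Bout(eg.Gait.TOLT, 25.0),
    ],
    seed=17,
)
bundle = eg.simulate_ride(plan, disagree_near_transitions=True)

streams = [
    eg.JudgeStream(judge_id=j, events=ev)
    for j, ev in enumerate(bundle.judge_events)
]
ts = eg.ts_timeline(bundle.label_events)
judges = eg.aggregate_judges(streams, float(ts.t[0]), float(ts.t[-1]))
cases = eg.pair_test_cases(ts, judges)
print(f"{len(cases)} valid test cases (disputed/unclassified ticks dropped)\n")

rows = eg.agreement_table(cases, ts, judges, [0, 1000, 2000], [0, 1000, 2000])
print("TS excl (ms)  judge excl (ms)  cases  agreement")
for r in rows:
    if r["ts_ms"] == r["judge_ms"]:
        print(f"{r['ts_ms']:>10.0f}  {r['judge_ms']:>14.0f}  {r['n_cases']:>5d}"
              f"  {100 * r['accuracy']:.2f}%")
print("\ndisagreements cluster at transitions (judge reaction lag), so")
print("agreement rises toward 100% as the exclusion radius grows.")
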
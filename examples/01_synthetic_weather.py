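"""Generate a synthetic summer weather record and aggregate it.

Builds a Tsukuba-like record (diurnal + seasonal sinusoids + autocorrelated
noise at a 10-min cadence), then resamples it to hourly blocks.
"""

import fieldfit as ff

ws = ff.synth_weather("2008-06-01", "2008-09-30", step=600, seed=42)
hourly = ff.resample_weather(ws, 3600)

july = hourly.frame.loc["2008-07-01":"2008-07-31"]
print(f"record: {len(ws)} steps at {ws.cadence} s cadence, attributes {ws.attributes}")
print("July hourly summary:")
print(july.describe().loc[["mean", "min", "max"]].round(2).to_string())
print(
    "\nTemperature peaks mid-afternoon and mid-season; precipitation is "
    "non-negative and summed (not averaged) when aggregating."
)
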
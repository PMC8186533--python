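"""Independent brute-force recomputation of the kinematic features.

Pure-Python loops and the statistics module only — deliberately shares no
code path with motorsig.features, so the two routes check each other.
"""

import math
import statistics


def oracle_step_series(t, x, y):
    """Naive speeds/accelerations/headings/directional change for one bout."""
    speeds, headings, dists = [], [], []
    for i in range(len(t) - 1):
        dt = t[i + 1] - t[i]
        dx = x[i + 1] - x[i]
        dy = y[i + 1] - y[i]
        d = math.hypot(dx, dy)
        dists.append(d)
        speeds.append(d / dt)
        if d == 0.0:
            headings.append(headings[-1] if headings else 0.0)
        else:
            headings.append(math.atan2(dy, dx))
    accels, dcs = [], []
    for i in range(len(speeds) - 1):
        dt = t[i + 1] - t[i]
        accels.append((speeds[i + 1] - speeds[i]) / dt)
        diff = headings[i + 1] - headings[i]
        while diff > math.pi:
            diff -= 2.0 * math.pi
        while diff <= -math.pi:
            diff += 2.0 * math.pi
        dcs.append(abs(diff) / dt)
    path = sum(dists)
    net = math.hypot(x[-1] - x[0], y[-1] - y[0])
    return {
        "speed": speeds,
        "acceleration": accels,
        "heading": headings,
        "dc": dcs,
        "path_length": path,
        "net_displacement": min(net, path),
    }


def oracle_task_features(bouts):
    """The 12 per-task features, recomputed naively from (t, x, y) triples."""
    series = [oracle_step_series(t, x, y) for t, x, y in bouts]
    speeds = [v for s in series for v in s["speed"]]
    accs = [v for s in series for v in s["acceleration"]]
    dcs = [v for s in series for v in s["dc"]]
    sths = [
        s["net_displacement"] / s["path_length"]
        for s in series
        if s["path_length"] > 0
    ]
    sths = [min(1.0, v) for v in sths]
    return {
        "MeanSpeed": statistics.fmean(speeds),
        "MaxSpeed": statistics.fmean(max(s["speed"]) for s in series),
        "MinSpeed": statistics.fmean(min(s["speed"]) for s in series),
        "sdSpeed": statistics.stdev(speeds),
        "MeanAcceleration": statistics.fmean(accs),
        "MaxAcceleration": statistics.fmean(
            max(s["acceleration"]) for s in series if s["acceleration"]
        ),
        "MinAcceleration": statistics.fmean(
            min(s["acceleration"]) for s in series if s["acceleration"]
        ),
        "sdAcceleration": statistics.stdev(accs),
        "STH": statistics.fmean(sths),
        "DC": statistics.fmean(dcs),
        "sdDC": statistics.stdev(dcs),
        "MeanLength": statistics.fmean(s["path_length"] for s in series),
    }
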
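"""One-off design scan: choose the synthetic carrier RMS (mV) so that the
normalised WAMP response to a ramp-hold-release envelope is as close to
proportional as possible at the default 10 mV threshold."""
import numpy as np, warnings
warnings.filterwarnings("ignore")
from emgface import synthetic, features
from emgface.muscles import measured_labels

def response(rms, seed=0):
    truth = synthetic.gen_activation_truth("B", 2.0, seed=seed)
    rec = synthetic.synth_semg(truth, synthetic.CrosstalkModel.identity(),
                               seed=seed, carrier_rms=rms)
    feat = features.minmax_normalise(features.wamp(features.bandpass(rec)))
    ch = feat.labels.index("LLSAN_L")
    # envelope on the feature time grid
    env = np.interp(feat.times, truth.times,
                    truth.values[truth.labels.index("LLSAN_L")])
    g = feat.values[ch]
    r = np.corrcoef(env, g)[0, 1]
    rmse = np.sqrt(np.mean((g - env)**2))
    return r, rmse

for rms in (10, 15, 20, 25, 30, 35, 40, 50, 70, 100):
    rs = [response(rms, s) for s in range(3)]
    r = np.mean([a for a, _ in rs]); e = np.mean([b for _, b in rs])
    print(f"rms={rms:5.0f} mV  corr(env, wamp_norm)={r:.5f}  rmse={e:.4f}")
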
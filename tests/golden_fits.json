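{
  "comment": "Reference fits on the seed-42, n=400 synthetic fixture (regenerated by the test). Values computed independently with R: survival::survreg(type='interval2', dist='gaussian'), stats::glm(binomial), MASS::polr(Hess=TRUE). Interval model uses a shared residual SD. Column order: const, group, pgs, pgs:group, female, female:group (ologit without const; thresholds appended).",
  "interval": {
    "params": [2.2584440047, -0.1409611902, -0.2685352663, 0.5107584173, 0.2502938369, -0.3609791958, 0.2892822311],
    "se": [0.14059661062, 0.21913803212, 0.09170450806, 0.15971832973, 0.18782373477, 0.30716662483, 0.04427798203],
    "z": [16.063289113, -0.643252971, -2.928266799, 3.197869763, 1.332599617, -1.175190163, 6.533320125],
    "p": [4.614208345e-58, 0.5200599668, 0.003408574197, 0.001384467911, 0.1826632311, 0.239918645, 6.432744126e-11],
    "llf": -482.9535
  },
  "logit": {
    "params": [0.169721573, -0.1707620676, -0.3760042712, 0.9103335566, 0.2011372957, -0.1820279701],
    "se": [0.1944154726, 0.3052548433, 0.1323579723, 0.2333803004, 0.2596665811, 0.4281210718],
    "z": [0.8729838772, -0.5594082168, -2.8408131735, 3.9006443768, 0.7745983132, -0.4251787219],
    "p": [0.3826718657, 0.5758831549, 0.004499866583, 9.593699152e-05, 0.4385770544, 0.6707063943],
    "llf": -266.6777
  },
  "ologit": {
    "params": [-0.447088591514, -0.472604862643, 1.007820509981, 0.039315268627, -0.002175484072],
    "se": [0.2626081234, 0.1157816203, 0.2035045249, 0.2277199376, 0.3672423234],
    "z": [-1.702493379851, -4.081864300049, 4.952324821407, 0.172647459138, -0.005923838113],
    "thresholds": [-2.642011273328, -1.356262710504, -0.335175541813, 0.688232273853, 2.012202150057],
    "threshold_se": [0.2346039218, 0.1912183585, 0.1797737247, 0.1828725374, 0.2160434585],
    "llf": -678.1072
  }
}
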
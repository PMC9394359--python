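{
 "coefficients": {
  "Intercept": -2.84,
  "neurons": 0.3902,
  "learning_rate": 0.2335,
  "momentum": 0.3684,
  "epochs": 0.0196,
  "train_function": 0.9651,
  "neurons*learning_rate": 0.1013,
  "neurons*momentum": -0.0805,
  "neurons*epochs": -0.039,
  "neurons*train_function": 0.4983,
  "learning_rate*momentum": -0.0448,
  "learning_rate*epochs": 0.0286,
  "learning_rate*train_function": 0.2241,
  "momentum*epochs": 0.0636,
  "momentum*train_function": 0.3759,
  "epochs*train_function": 0.0218,
  "neurons^2": 0.4167,
  "learning_rate^2": 0.2801,
  "momentum^2": -0.2819,
  "epochs^2": -0.0985
 },
 "anova_statistics": {
  "model_f": 15.35,
  "r2": 0.8794,
  "adjusted_r2": 0.8221,
  "predicted_r2": 0.7183,
  "adequate_precision": 14.8721,
  "lack_of_fit_f": 0.768,
  "model_df": 19,
  "residual_df": 40,
  "lack_of_fit_df": 30,
  "pure_error_df": 10,
  "total_df": 59
 },
 "term_f": {
  "neurons": 18.32,
  "learning_rate": 6.56,
  "momentum": 16.33,
  "epochs": 0.0464,
  "train_function": 186.76,
  "neurons*learning_rate": 1.1,
  "neurons*momentum": 0.6924,
  "neurons*epochs": 0.1624,
  "neurons*train_function": 29.88,
  "learning_rate*momentum": 0.2149,
  "learning_rate*epochs": 0.0874,
  "learning_rate*train_function": 6.04,
  "momentum*epochs": 0.4319,
  "momentum*train_function": 17.0,
  "epochs*train_function": 0.0574,
  "neurons^2": 3.01,
  "learning_rate^2": 1.36,
  "momentum^2": 1.38,
  "epochs^2": 0.1681
 },
 "predicted_ln": [
  -3.91,
  -0.7624,
  -4.08,
  -2.01,
  -2.03,
  -3.8,
  -4.09,
  -3.46,
  -1.14,
  -3.35,
  -3.8,
  -3.32,
  -3.8,
  -3.43,
  -0.5696,
  -1.87,
  -0.5575,
  -0.4826,
  -3.5,
  -1.87,
  -3.57,
  0.6025,
  -3.8,
  -3.53,
  -0.6975,
  -2.92,
  -2.05,
  -2.05,
  0.4133,
  -3.8,
  -3.57,
  -2.83,
  -1.87,
  -3.53,
  -1.14,
  -3.1,
  -3.52,
  -3.8,
  -3.24,
  -3.5,
  -1.87,
  -3.67,
  -1.82,
  -1.41,
  -3.66,
  -3.9,
  -2.35,
  -1.93,
  -3.76,
  -3.28,
  -1.85,
  -3.28,
  -1.48,
  -1.87,
  -3.68,
  -3.74,
  -3.5,
  -3.8,
  -1.87,
  -2.9
 ],
 "center_point_prediction": {
  "trainlm": -3.8,
  "traingdm": -1.87
 }
}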
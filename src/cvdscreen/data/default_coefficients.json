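{
  "betas": {
    "female": {
      "age": 4.519234,
      "antihypertensive": 0.564904,
      "diabetes": 0.988582,
      "hdl_cholesterol": -1.271035,
      "smoker": 0.917969,
      "systolic_bp": 2.542069,
      "total_cholesterol": 1.412261
    },
    "male": {
      "age": 3.674681,
      "antihypertensive": 0.459335,
      "diabetes": 0.803836,
      "hdl_cholesterol": -1.033504,
      "smoker": 0.74642,
      "systolic_bp": 2.067008,
      "total_cholesterol": 1.148338
    }
  },
  "covariates": [
    "age",
    "total_cholesterol",
    "hdl_cholesterol",
    "systolic_bp",
    "antihypertensive",
    "smoker",
    "diabetes"
  ],
  "mean_lp": {
    "female": 32.003739,
    "male": 26.267829
  },
  "s0_10y": {
    "female": 0.98475,
    "male": 0.972031
  },
  "transforms": {
    "age": "log",
    "antihypertensive": "identity",
    "diabetes": "identity",
    "hdl_cholesterol": "log",
    "smoker": "identity",
    "systolic_bp": "log",
    "total_cholesterol": "log"
  },
  "version": "synthetic-default-1"
}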
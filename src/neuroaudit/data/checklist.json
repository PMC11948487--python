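{
  "title": "Reproducibility and validity checklist for machine learning on neural data",
  "version": "1.0",
  "answers": ["yes", "no", "unclear", "n/a"],
  "categories": [
    {
      "id": "data",
      "name": "On data and definition of training and testing set",
      "note": "Training and testing data should be statistically independent, such that they are not only different data but also not dependent on each other.",
      "items": [
        {"id": "data-1", "text": "Is there appropriate detail on all data sources (e.g. origin of the data, relevant summary statistics, preprocessing, etc)?"},
        {"id": "data-2", "text": "For data based on epochs/time windows of neural signals (as typical in neural engineering applications), training epochs and testing epochs do not overlap and are not consecutive to each other."},
        {"id": "data-3", "text": "If the data acquisition protocol has a block structure (e.g. same class label for all data points of that block), then the test data comes from different blocks than the training data."}
      ]
    },
    {
      "id": "hyperparameters",
      "name": "On parameters and hyperparameters selection and optimization",
      "note": "In general, the parameters and settings/hyperparameters should be selected on training/validation data that are completely independent of the testing data.",
      "items": [
        {"id": "hyper-1", "text": "Are the assumptions of the machine learning approaches or models clearly defined and documented?"},
        {"id": "hyper-2", "text": "Feature selection was performed using training data only (i.e. not using testing data and not using all data)."},
        {"id": "hyper-3", "text": "Machine learning settings/hyperparameters are optimized only on training data. This should be the case not only for a classifier, but also for any algorithm whose settings are optimized on data."},
        {"id": "hyper-4", "text": "Any normalization parameters (e.g. data mean and standard deviation) was estimated on training data only. Testing data should not be included in this estimation (e.g. this estimation should not be made on all available data)."},
        {"id": "hyper-5", "text": "Hyperparameters (e.g. regularization parameters of SVM or Logistic regression, learning rate, batch size, etc) were selected on training and/or validation data only."},
        {"id": "hyper-6", "text": "The architecture of a neural network was chosen on training/validation data only."}
      ]
    },
    {
      "id": "metrics",
      "name": "On performance metrics",
      "note": null,
      "items": [
        {"id": "metric-1", "text": "Are the chosen performance metrics clearly defined and motivated?"},
        {"id": "metric-2", "text": "For unbalanced test data (e.g. a significantly different amount of testing data per class), was a performance metric that can handle unbalanced data used (e.g. area under the ROC curve or balanced accuracy)?"},
        {"id": "metric-3", "text": "For a test set with little data, was the chance level performance metric reported (either through analytical calculations or permutation testing) and compared to the actual performance?"},
        {"id": "metric-4", "text": "Are measures of uncertainty clearly defined and appropriate?"}
      ]
    },
    {
      "id": "conclusions",
      "name": "On scientific conclusions",
      "note": null,
      "items": [
        {"id": "concl-1", "text": "Are the key scientific questions clearly related to model results?"},
        {"id": "concl-2", "text": "Is it clear how the validation technique relates to the scientific questions?"},
        {"id": "concl-3", "text": "Is the practical significance of the performance metrics clearly stated?"},
        {"id": "concl-4", "text": "Are statistics run on model results?"},
        {"id": "concl-5", "text": "Are statistical assumptions clearly defined?"},
        {"id": "concl-6", "text": "Is it clear what level of generalization (e.g. inter-subject, inter-cohort, inter-genotype, etc) is tested?"},
        {"id": "concl-7", "text": "Are the limitations of the results clearly stated?"},
        {"id": "concl-8", "text": "Are alternative explanations for performance considered?"},
        {"id": "concl-9", "text": "Are there concerns about bias or fairness?"},
        {"id": "concl-10", "text": "Were specific metrics on bias and fairness identified and evaluated?"}
      ]
    },
    {
      "id": "future_use",
      "name": "On future use of results and developed technologies",
      "note": null,
      "items": [
        {"id": "future-1", "text": "Will the data be publicly available?"},
        {"id": "future-2", "text": "Will data include necessary metadata for reproducing results?"},
        {"id": "future-3", "text": "Has the data been properly anonymized according to data privacy protection laws and good practices?"},
        {"id": "future-4", "text": "Does anonymization of the data prevent reproduction of the results?"},
        {"id": "future-5", "text": "Is the data stored in a trustworthy repository?"},
        {"id": "future-6", "text": "Is the data license stated?"},
        {"id": "future-7", "text": "Will the code be released in full, including training code, evaluation code, and visualizations?"},
        {"id": "future-8", "text": "Is the code license stated?"},
        {"id": "future-9", "text": "Are dependencies and software versions included?"},
        {"id": "future-10", "text": "Is it stated which results can be fully replicated by the code?"},
        {"id": "future-11", "text": "Is there an appropriately detailed guide on how to use the code?"},
        {"id": "future-12", "text": "Will the trained machine learning model be released?"},
        {"id": "future-13", "text": "Is it clear what resources are necessary to run the code (computational resources, software environment, computational complexity)?"},
        {"id": "future-14", "text": "Is it stated how long any released material will be available?"},
        {"id": "future-15", "text": "It is stated whether permanent record will be created, typically a digital object identifier (DOI)?"}
      ]
    }
  ]
}
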
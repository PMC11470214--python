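{
  "description": "Default French lexicon for psychological-trauma symptom mentions in forensic medical certificates. Terms are matched after normalization (lower-case, accents stripped, punctuation collapsed) with a length-banded edit-distance tolerance.",
  "concepts": {
    "sleep_disorder": {
      "terms": [
        "trouble du sommeil",
        "troubles du sommeil",
        "difficulte d endormissement",
        "difficultes d endormissement",
        "reveils frequents",
        "reveil matinal precoce",
        "reveils nocturnes",
        "cauchemars",
        "insomnie"
      ]
    },
    "loss_of_appetite": {
      "terms": [
        "perte d appetit",
        "manque d appetit",
        "inappetence",
        "perte de l appetit"
      ]
    },
    "stress_symptoms": {
      "terms": [
        "souvenirs recurrents",
        "reviviscences",
        "evitement",
        "hypervigilance",
        "etat de stress",
        "flashbacks"
      ]
    },
    "pain": {
      "terms": [
        "douleur",
        "douleurs",
        "douloureux",
        "douloureuse",
        "cephalees",
        "endolori"
      ]
    },
    "fear": {
      "terms": [
        "peur",
        "apeure",
        "apeuree",
        "crainte",
        "craintes",
        "angoisse",
        "angoissee",
        "frayeur",
        "effroi",
        "terreur"
      ]
    }
  }
}
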
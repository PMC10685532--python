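{
  "char_map": {
    "ي": "ی",
    "ك": "ک",
    "ى": "ی",
    "أ": "ا",
    "إ": "ا",
    "ؤ": "و",
    "ئ": "ی",
    "ة": "ه",
    "اب": "آب",
    "اقا": "آقا",
    "ازمایش": "آزمایش",
    "اسانسور": "آسانسور",
    "امپول": "آمپول"
  },
  "spelling_variants": {
    "اطاق": "اتاق",
    "بلیط": "بلیت",
    "باطری": "باتری",
    "طهران": "تهران",
    "پیر مرد": "پیرمرد",
    "شیمی درمانی": "شیمی‌درمانی",
    "شیمیدرمانی": "شیمی‌درمانی"
  },
  "suffixes": ["ترین", "تر", "هایش", "هایم", "های", "ها"],
  "prefixes": ["نمی", "درمی", "برمی", "می", "بی"],
  "punctuation": [".", ",", "!", "?", "؟", "،", "؛", ":", ";", "(", ")", "[", "]", "«", "»", "\"", "'", "…", "_", "/"],
  "elongation_chars": ["ـ"],
  "shifters": ["نا", "ن", "ضد"],
  "protected_words": ["ناراحت", "ناامید", "نگران", "ناهار", "نامناسب"],
  "stopwords_file": "stopwords.txt"
}
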